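"""Deterministic generators for phantoms and planted sparse problems.

Two kinds of ground truth back the test suite and the examples:

* *Phantom pairs* — a shared pseudo-color scene (smooth radial intensity
  blobs plus sharp ring/box edges, loosely imitating functional nuclear-
  medicine pseudo-color) split into two complementary sources, each
  revealing a different spatial region.  The truth is recoverable only by
  combining both, which is exactly the situation a fusion rule must handle.
* *Sparse problems* — a planted unit-norm multivector dictionary and
  k-sparse coefficient matrix, with the observation assembled through the
  geometric product, for pursuit/dictionary-recovery oracles.

Every generator is a pure function of its spec: same seed, same bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ga import ga_matvec
from .pursuit import GADictionary, GACoeffMatrix

__all__ = ["PhantomSpec", "SparseProblem", "make_phantom_pair", "make_sparse_problem"]

_DEFAULT_PALETTE = (
    (0.9, 0.2, 0.1),
    (0.1, 0.7, 0.9),
    (0.9, 0.8, 0.1),
    (0.2, 0.9, 0.3),
    (0.7, 0.2, 0.9),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a complementary phantom pair."""

    size: int = 64
    seed: int = 0
    n_blobs: int = 5
    palette: tuple = _DEFAULT_PALETTE
    edge_density: float = 0.5  # expected sharp structures per 64² of area
    psf_sigma: float = 0.6  # imaging-system point-spread blur, pixels
    complement_mode: str = "halves"  # halves | bands | checker
    noise_sd: float = 0.0


@dataclass
class SparseProblem:
    """A planted sparse-coding instance Q = D_true · A_true (+ noise)."""

    D_true: GADictionary
    A_true: GACoeffMatrix
    Q: np.ndarray  # (N, K, 4)
    k: int
    seed: int
    noise_sd: float
    coherence: float


def _truth_scene(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    img = np.zeros((s, s, 3))
    palette = np.asarray(spec.palette, dtype=float)
    for b in range(spec.n_blobs):
        cy, cx = rng.uniform(0.1 * s, 0.9 * s, size=2)
        sigma = rng.uniform(0.08 * s, 0.25 * s)
        color = palette[b % len(palette)]
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        img += bump[..., None] * color[None, None, :]
    n_edges = max(1, int(round(spec.edge_density * (s / 64.0) ** 2 * 4)))
    for _ in range(n_edges):
        cy, cx = rng.uniform(0.15 * s, 0.85 * s, size=2)
        r = rng.uniform(0.06 * s, 0.2 * s)
        width = max(1.0, 0.02 * s)
        color = palette[rng.integers(len(palette))]
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        ring = (np.abs(dist - r) < width).astype(float)
        img += 0.8 * ring[..., None] * color[None, None, :]
    if spec.psf_sigma > 0:
        # every real acquisition has a point-spread function; functional
        # nuclear-medicine pseudo-color in particular is visibly band-limited
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(img, (spec.psf_sigma, spec.psf_sigma, 0))
    peak = img.max()
    if peak > 1.0:
        img /= peak
    return img


def _complement_masks(mode: str, size: int) -> tuple:
    yy, xx = np.mgrid[0:size, 0:size]
    if mode == "halves":
        m1 = (xx < size // 2).astype(float)
    elif mode == "bands":
        band = max(1, size // 8)
        m1 = ((yy // band) % 2 == 0).astype(float)
    elif mode == "checker":
        block = max(1, size // 8)
        m1 = (((yy // block) + (xx // block)) % 2 == 0).astype(float)
    else:
        raise ValueError(f"unknown complement_mode {mode!r}")
    return m1, 1.0 - m1


def make_phantom_pair(spec: PhantomSpec):
    """Build (img1, img2, truth): two complementary views of one scene.

    The two sources carry disjoint spatial supports (per ``complement_mode``)
    so that ``img1 + img2 == truth`` before noise; Gaussian noise of sd
    ``noise_sd`` is added per source and everything is clipped to [0, 1].
    """
    if spec.size < 32:
        raise ValueError("phantom size must be ≥ 32")
    rng = np.random.default_rng(spec.seed)
    truth = _truth_scene(spec, rng)
    m1, m2 = _complement_masks(spec.complement_mode, spec.size)
    img1 = truth * m1[..., None]
    img2 = truth * m2[..., None]
    if spec.noise_sd > 0:
        img1 = img1 + rng.normal(0.0, spec.noise_sd, img1.shape)
        img2 = img2 + rng.normal(0.0, spec.noise_sd, img2.shape)
    return np.clip(img1, 0, 1), np.clip(img2, 0, 1), truth


def _embedding_coherence(atoms: np.ndarray) -> float:
    """Max |inner product| between distinct vec'd unit atoms."""
    A = atoms.transpose(0, 2, 1).reshape(-1, atoms.shape[1])
    G = np.abs(A.T @ A)
    np.fill_diagonal(G, 0.0)
    return float(G.max())


def make_sparse_problem(
    N: int,
    M: int,
    k: int,
    K_cols: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    gains: str = "ga",
) -> SparseProblem:
    """Plant a k-sparse multivector coding problem.

    Each column of ``A_true`` has exactly k nonzero entries with magnitudes
    in [0.5, 2].  ``gains="ga"`` draws full multivector coefficients;
    ``gains="scalar"`` draws signed real scalars — the latter pins the GA
    gauge of the planted atoms and is what dictionary-recovery scoring needs.
    The observation is ``Q = D_true · A_true`` plus optional Gaussian noise.
    """
    if k >= N or N > M:
        raise ValueError(f"infeasible problem: need k < N ≤ M, got k={k}, N={N}, M={M}")
    rng = np.random.default_rng(seed)
    D_true = GADictionary.normalized(rng.standard_normal((N, M, 4)))
    codes = np.zeros((M, K_cols, 4))
    supports = []
    for j in range(K_cols):
        sup = rng.choice(M, size=k, replace=False)
        mags = rng.uniform(0.5, 2.0, size=k)
        if gains == "scalar":
            coeff = np.zeros((k, 4))
            coeff[:, 0] = mags * rng.choice([-1.0, 1.0], size=k)
        elif gains == "ga":
            direc = rng.standard_normal((k, 4))
            direc /= np.linalg.norm(direc, axis=1, keepdims=True)
            coeff = direc * mags[:, None]
        else:
            raise ValueError(f"unknown gains mode {gains!r}")
        codes[sup, j, :] = coeff
        supports.append(tuple(int(s) for s in sorted(sup)))
    Q = np.stack([ga_matvec(D_true.atoms, codes[:, j, :]) for j in range(K_cols)], axis=1)
    if noise_sd > 0:
        Q = Q + rng.normal(0.0, noise_sd, Q.shape)
    return SparseProblem(
        D_true=D_true,
        A_true=GACoeffMatrix(codes=codes, supports=supports),
        Q=Q,
        k=k,
        seed=seed,
        noise_sd=noise_sd,
        coherence=_embedding_coherence(D_true.atoms),
    )
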