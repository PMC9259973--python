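"""End-to-end multivector sparse-representation fusion of two color images.

Pipeline (both sources co-registered, identical shapes):

1. encode each image as a multivector field (R→γ1, G→γ2, B→γ12);
2. slide an n×n window (default step 1) over both and flatten the blocks
   into length-n² multivector columns;
3. train **one shared dictionary** on the pooled patches of both sources
   with K-GASVD (a random subsample caps the training set size);
4. sparse-code each source's patches with GAOMP against that dictionary;
5. fuse column-wise by the L1-max rule: keep whichever source's coefficient
   column has the larger L1 norm (Σ of entry magnitudes; ties → source 1);
6. reconstruct fused patches as dictionary·coefficients, overlap-average
   them back into an image, and decode.

The fused coefficient matrix is a pure selection — every column bit-matches
one of the two source columns — and the whole run is deterministic given the
configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dictionary import TrainState, kgasvd, _stack
from .image import GAImage, PatchSet, decode_image, encode_image, extract_patches, reconstruct_image
from .pursuit import GACoeffMatrix, GACoeffVector, GADictionary, code_patchset

__all__ = ["FusionConfig", "FusionResult", "l1_norm", "fuse_coefficients", "fuse_images"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """Tunable parameters of a fusion run.

    ``patch_size`` n and ``step`` control the sliding window (n=8, step 1 by
    default); ``n_atoms`` M and ``sparsity`` J the dictionary and the pursuit
    budget; ``train_iters`` the K-GASVD iterations; ``max_train_patches``
    caps the pooled training subsample.  ``tol`` is the pursuit's residual
    tolerance relative to each column's norm, and ``e0_tolerance`` the
    audit threshold for scalar residue discarded at decode time.
    """

    patch_size: int = 8
    step: int = 1
    n_atoms: int = 256
    sparsity: int = 8
    train_iters: int = 20
    tol: float = 1e-6
    seed: int = 0
    e0_tolerance: float = 1e-2
    max_train_patches: int = 10000

    def __post_init__(self):
        if self.patch_size < 2:
            raise ValueError("patch_size must be ≥ 2")
        if self.step < 1:
            raise ValueError("step must be ≥ 1")
        if self.sparsity < 1:
            raise ValueError("sparsity must be ≥ 1")
        if self.train_iters < 1:
            raise ValueError("train_iters must be ≥ 1")
        if self.n_atoms < self.patch_size**2:
            log.warning(
                "n_atoms=%d below patch dimension n²=%d; the dictionary is undercomplete",
                self.n_atoms,
                self.patch_size**2,
            )


@dataclass
class FusionResult:
    """Everything a fusion run produced."""

    fused_image: GAImage
    fused: np.ndarray  # decoded H×W×3 array in [0, 1]
    A1: GACoeffMatrix
    A2: GACoeffMatrix
    AF: GACoeffMatrix
    dictionary: GADictionary
    mask: np.ndarray  # per-column winner: 1 or 2
    train_state: TrainState | None = None


def l1_norm(a) -> float:
    """L1 norm of a multivector coefficient vector: Σ magnitude(entry).

    Accepts a GACoeffVector or a bare (M, 4) array; the magnitude of an
    entry plays the role of the absolute value of a scalar element.
    """
    entries = a.entries if isinstance(a, GACoeffVector) else np.asarray(a, dtype=float)
    return float(np.sqrt(np.sum(entries**2, axis=-1)).sum())


def fuse_coefficients(A1: GACoeffMatrix, A2: GACoeffMatrix):
    """Column-wise L1-max selection between two coefficient matrices.

    Column i of the result is A1's column when its L1 norm is ≥ A2's (ties
    go to source 1), else A2's.  Returns (AF, mask) with mask[i] ∈ {1, 2}.
    """
    C1, C2 = A1.codes, A2.codes
    if C1.shape != C2.shape:
        raise ValueError(f"coefficient shapes differ: {C1.shape} vs {C2.shape}")
    n1 = np.sqrt(np.sum(C1**2, axis=-1)).sum(axis=0)
    n2 = np.sqrt(np.sum(C2**2, axis=-1)).sum(axis=0)
    take1 = n1 >= n2
    mask = np.where(take1, 1, 2).astype(np.int8)
    codes = np.where(take1[None, :, None], C1, C2)
    supports = [A1.supports[j] if take1[j] else A2.supports[j] for j in range(C1.shape[1])]
    return GACoeffMatrix(codes=codes, supports=supports), mask


def fuse_images(img1: np.ndarray, img2: np.ndarray, cfg: FusionConfig | None = None) -> FusionResult:
    """Fuse two co-registered H×W×3 images; see the module docstring."""
    cfg = cfg or FusionConfig()
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError(f"source shapes differ: {img1.shape} vs {img2.shape}")
    if img1.ndim != 3 or img1.shape[-1] != 3:
        raise ValueError("sources must be H×W×3 arrays")

    ga1 = encode_image(img1)
    ga2 = encode_image(img2)
    P1 = extract_patches(ga1, cfg.patch_size, cfg.step)
    P2 = extract_patches(ga2, cfg.patch_size, cfg.step)

    pooled = np.concatenate([P1.vectors, P2.vectors], axis=1)
    K_pool = pooled.shape[1]
    if K_pool > cfg.max_train_patches:
        rng = np.random.default_rng(cfg.seed)
        pick = rng.choice(K_pool, size=cfg.max_train_patches, replace=False)
        pooled = pooled[:, np.sort(pick), :]
        log.info("training on %d of %d pooled patches", cfg.max_train_patches, K_pool)

    state = kgasvd(pooled, M=cfg.n_atoms, J=cfg.sparsity, iters=cfg.train_iters, seed=cfg.seed, tol=cfg.tol)
    D = state.dictionary

    A1 = code_patchset(P1, D, J=cfg.sparsity, tol=cfg.tol)
    A2 = code_patchset(P2, D, J=cfg.sparsity, tol=cfg.tol)
    AF, mask = fuse_coefficients(A1, A2)

    XF = D.real_matrix @ _stack(AF.codes)  # (4N, K) fused patch columns
    fused_patches = PatchSet(
        vectors=XF.reshape(D.n_features, 4, -1).transpose(0, 2, 1),
        positions=P1.positions,
        patch_size=cfg.patch_size,
        source_shape=P1.source_shape,
        step=cfg.step,
    )
    fused_ga = reconstruct_image(fused_patches)
    fused = decode_image(fused_ga, e0_tolerance=cfg.e0_tolerance)
    return FusionResult(
        fused_image=fused_ga,
        fused=fused,
        A1=A1,
        A2=A2,
        AF=AF,
        dictionary=D,
        mask=mask,
        train_state=state,
    )
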