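"""GAOMP: orthogonal matching pursuit for multivector-valued signals.

Solves the sparse model  min ‖a‖₀  s.t. q ≈ D a  greedily: at each step the
residual is correlated with every atom through the reversion-conjugated
geometric product

    c_m = Σ_i  reverse(D[i,m]) · r[i],

whose scalar part equals the real-embedding inner product ⟨vec(d_m), vec(r)⟩
and whose magnitude equals the norm of the residual's projection
coefficients onto the 4-dimensional real subspace spanned by the GA
multiples of atom m.  The atom with the largest correlation magnitude joins
the active set (ties → lowest index), the coefficients are re-solved by
least squares on the real embedding, and the residual is updated.  The
pursuit stops at ``J`` atoms or when the residual norm falls below
``tol·‖q‖``.

When every input has only a scalar (e0) component the procedure reduces
exactly to classical scalar OMP.

The batch coder shares the same mathematics but solves each column's least
squares through the normal equations on a precomputed embedded Gram matrix
(re-solved from scratch every iteration), which is what makes coding tens of
thousands of patch columns practical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as _sparse

from .ga import gp, reverse, real_embedding

__all__ = [
    "GADictionary",
    "GACoeffVector",
    "GACoeffMatrix",
    "ga_correlations",
    "gaomp",
    "code_patchset",
]

log = logging.getLogger(__name__)

_UNIT_NORM_TOL = 1e-10


@dataclass
class GADictionary:
    """An N×M multivector dictionary whose atoms have unit GA Frobenius norm.

    ``atoms`` has shape (N, M, 4); the norm of an atom is the root-sum-square
    of its 4N real components.
    """

    atoms: np.ndarray
    atom_norms: np.ndarray = field(init=False)

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 3 or self.atoms.shape[-1] != 4:
            raise ValueError(f"dictionary atoms need shape (N, M, 4), got {self.atoms.shape}")
        if not np.isfinite(self.atoms).all():
            raise ValueError("dictionary contains non-finite values")
        self.atom_norms = np.sqrt(np.sum(self.atoms**2, axis=(0, 2)))
        if (self.atom_norms < _UNIT_NORM_TOL).any():
            raise ValueError("dictionary contains a zero atom")
        if np.abs(self.atom_norms - 1.0).max() > _UNIT_NORM_TOL:
            raise ValueError("dictionary atoms must be unit-norm (use GADictionary.normalized)")
        self._real = None
        self._gram = None

    @classmethod
    def normalized(cls, atoms: np.ndarray) -> "GADictionary":
        atoms = np.asarray(atoms, dtype=float)
        norms = np.sqrt(np.sum(atoms**2, axis=(0, 2)))
        if (norms < _UNIT_NORM_TOL).any():
            raise ValueError("cannot normalize a zero atom")
        return cls(atoms / norms[None, :, None])

    @property
    def n_features(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def real_matrix(self) -> np.ndarray:
        """Cached 4N×4M real embedding of the dictionary."""
        if self._real is None:
            self._real = real_embedding(self.atoms)
        return self._real

    @property
    def gram(self) -> np.ndarray:
        """Cached 4M×4M Gram matrix of the real embedding."""
        if self._gram is None:
            Dr = self.real_matrix
            self._gram = Dr.T @ Dr
        return self._gram


@dataclass
class GACoeffVector:
    """A length-M sparse multivector coefficient vector."""

    entries: np.ndarray  # (M, 4)
    support: tuple  # atom indices in selection order
    residual_norm: float = 0.0
    residual_history: np.ndarray | None = None

    @property
    def l0(self) -> int:
        return len(self.support)


@dataclass
class GACoeffMatrix:
    """Column-stacked sparse codes: ``codes`` is (M, K, 4)."""

    codes: np.ndarray
    supports: list
    residual_norms: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> GACoeffVector:
        return GACoeffVector(entries=self.codes[:, j, :], support=tuple(self.supports[j]))


def ga_correlations(D: GADictionary, r: np.ndarray) -> np.ndarray:
    """Correlation multivectors c_m = Σ_i reverse(D[i,m])·r[i], shape (M, 4)."""
    r = np.asarray(r, dtype=float)
    return gp(reverse(D.atoms), r[:, None, :]).sum(axis=0)


def _batch_omp(Q: np.ndarray, D: GADictionary, J: int, tol: float):
    """Lockstep GAOMP over the K columns of Q (shape (N, K, 4)).

    Returns (codes (M,K,4), supports, res_history (K, ≤J+1) padded with the
    final value).  Columns are mutually independent; the result does not
    depend on their order.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.isfinite(Q).all():
        raise ValueError("input contains non-finite values")
    N, K, _ = Q.shape
    if N != D.n_features:
        raise ValueError(f"patch length {N} does not match dictionary rows {D.n_features}")
    if J < 1:
        raise ValueError("sparsity budget J must be ≥ 1")
    M = D.n_atoms
    J = min(J, M)
    Dr = D.real_matrix
    Gram = D.gram

    Qr = Q.transpose(0, 2, 1).reshape(4 * N, K)
    Corr0 = Dr.T @ Qr  # (4M, K)
    qnorm2 = np.einsum("ij,ij->j", Qr, Qr)
    tol_abs2 = (tol * np.sqrt(qnorm2)) ** 2

    X = np.zeros((4 * M, K))
    active = np.full((K, J), -1, dtype=int)
    selected = np.zeros((M, K), dtype=bool)
    res2 = qnorm2.copy()
    history = [np.sqrt(res2)]
    finished = res2 <= tol_abs2 + 1e-300

    four = np.arange(4)
    for t in range(J):
        live = np.nonzero(~finished)[0]
        if live.size == 0:
            break
        if t == 0:
            Corr = Corr0
        else:
            Xs = _sparse.csr_matrix(X.T)
            Corr = Corr0 - (Xs @ Gram).T
        mag2 = np.einsum("mck,mck->mk", Corr.reshape(M, 4, K), Corr.reshape(M, 4, K))
        mag2 = np.where(selected, -1.0, mag2)
        sel = np.argmax(mag2[:, live], axis=0)
        active[live, t] = sel
        selected[sel, live] = True

        idx = active[live, : t + 1]  # (g, t+1)
        bidx = (idx[:, :, None] * 4 + four).reshape(live.size, 4 * (t + 1))
        Gsub = Gram[bidx[:, :, None], bidx[:, None, :]]
        rhs = Corr0[bidx, live[:, None]]
        try:
            x = np.linalg.solve(Gsub, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            x = np.empty_like(rhs)
            for g in range(live.size):
                x[g] = np.linalg.lstsq(Gsub[g], rhs[g], rcond=None)[0]
        new_res2 = qnorm2[live] - np.einsum("gi,gi->g", x, rhs)
        bad = ~np.isfinite(new_res2) | (new_res2 > res2[live] + 1e-9)
        if bad.any():
            for g in np.nonzero(bad)[0]:
                x[g] = np.linalg.lstsq(Gsub[g], rhs[g], rcond=None)[0]
                new_res2[g] = qnorm2[live[g]] - x[g] @ rhs[g]
            log.debug("batch OMP: %d ill-conditioned columns re-solved by lstsq", int(bad.sum()))
        new_res2 = np.maximum(new_res2, 0.0)

        X[:, live] = 0.0
        X[bidx, live[:, None]] = x
        res2[live] = new_res2
        history.append(np.sqrt(res2))
        finished |= res2 <= tol_abs2 + 1e-300

    codes = X.reshape(M, 4, K).transpose(0, 2, 1)
    supports = [tuple(int(a) for a in row if a >= 0) for row in active]
    res_hist = np.stack(history, axis=1)  # (K, iters+1)
    return codes, supports, res_hist


def gaomp(q: np.ndarray, D: GADictionary, J: int = 8, tol: float = 1e-6) -> GACoeffVector:
    """Sparse-code one multivector vector ``q`` (shape (N, 4)) against D.

    ``tol`` is relative to ‖q‖.  The residual norm is non-increasing across
    iterations; after each least-squares re-solve the residual is orthogonal
    (in the real embedding) to every active atom's GA multiples.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError(f"expected q of shape (N, 4), got {q.shape}")
    codes, supports, hist = _batch_omp(q[:, None, :], D, J, tol)
    return GACoeffVector(
        entries=codes[:, 0, :],
        support=supports[0],
        residual_norm=float(hist[0, -1]),
        residual_history=hist[0],
    )


def code_patchset(P, D: GADictionary, J: int = 8, tol: float = 1e-6) -> GACoeffMatrix:
    """Sparse-code every column of a PatchSet (or bare (N, K, 4) array)."""
    Q = P.vectors if hasattr(P, "vectors") else np.asarray(P, dtype=float)
    if Q.shape[1] == 0:
        M = D.n_atoms
        return GACoeffMatrix(codes=np.zeros((M, 0, 4)), supports=[], residual_norms=np.zeros(0))
    codes, supports, hist = _batch_omp(Q, D, J, tol)
    return GACoeffMatrix(codes=codes, supports=supports, residual_norms=hist[:, -1])
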