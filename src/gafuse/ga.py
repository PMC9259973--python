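"""Arithmetic for the 4-dimensional geometric (Clifford) algebra G2.

G2 is generated by two orthonormal vectors ``γ1, γ2`` with ``γi² = 1``; a
general element (multivector) is

    a = e0 · 1 + e1 · γ1 + e2 · γ2 + e12 · γ12,        γ12 = γ1 γ2,

and the geometric product follows from the anticommutation rule
``γ1 γ2 = −γ2 γ1`` (so ``γ12² = −1``).  One multivector carries one color
pixel (R, G, B on the three non-scalar blades) or one sparse coefficient.

Throughout the package multivector arrays are plain ``float64`` ndarrays
whose **last axis has length 4** in the fixed component order
``(e0, e1, e2, e12)``.  All functions here broadcast over leading axes, so a
single multivector is simply shape ``(4,)``.

The real 4×4 matrix representation used by the linear-algebra layer comes in
both orientations:

* :func:`to_real_matrix` — the operator of *right* multiplication by ``a``
  (``M(a) @ vec(b) == vec(b·a)``), an anti-homomorphism;
* :func:`left_matrix` — the operator of *left* multiplication
  (``L(a) @ vec(b) == vec(a·b)``), a homomorphism, which is what the block
  embedding of a dictionary–coefficient product ``q = D a`` needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Multivector",
    "SCALAR",
    "G1",
    "G2V",
    "G12",
    "mv",
    "gp",
    "reverse",
    "magnitude",
    "to_real_matrix",
    "left_matrix",
    "real_embedding",
    "vec",
    "unvec",
    "ga_matvec",
    "ga_lstsq",
]

log = logging.getLogger(__name__)

_COMPONENTS = ("e0", "e1", "e2", "e12")


@dataclass(frozen=True)
class Multivector:
    """A single G2 element with components (scalar, γ1, γ2, γ12)."""

    e0: float = 0.0
    e1: float = 0.0
    e2: float = 0.0
    e12: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.e0, self.e1, self.e2, self.e12], dtype=float)

    @staticmethod
    def from_array(a: np.ndarray) -> "Multivector":
        a = np.asarray(a, dtype=float).reshape(4)
        return Multivector(*a.tolist())

    def __mul__(self, other):
        if isinstance(other, Multivector):
            return Multivector.from_array(gp(self.as_array(), other.as_array()))
        return Multivector.from_array(self.as_array() * float(other))

    __rmul__ = __mul__

    def __add__(self, other: "Multivector") -> "Multivector":
        return Multivector.from_array(self.as_array() + other.as_array())

    def __sub__(self, other: "Multivector") -> "Multivector":
        return Multivector.from_array(self.as_array() - other.as_array())

    def __neg__(self) -> "Multivector":
        return Multivector.from_array(-self.as_array())


#: Basis elements, convenient in tests and examples.
SCALAR = Multivector(1.0, 0.0, 0.0, 0.0)
G1 = Multivector(0.0, 1.0, 0.0, 0.0)
G2V = Multivector(0.0, 0.0, 1.0, 0.0)
G12 = Multivector(0.0, 0.0, 0.0, 1.0)


def mv(e0=0.0, e1=0.0, e2=0.0, e12=0.0) -> np.ndarray:
    """Build a single multivector as a length-4 component array."""
    return np.array([e0, e1, e2, e12], dtype=float)


def _comp(a: np.ndarray):
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != 4:
        raise ValueError(f"multivector arrays need a trailing axis of 4, got shape {a.shape}")
    return a[..., 0], a[..., 1], a[..., 2], a[..., 3]


def gp(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geometric product ``a·b``, broadcasting over leading axes.

    Follows the G2 multiplication table: γ1² = γ2² = 1, γ12² = −1,
    γ1γ2 = γ12 = −γ2γ1, γ1γ12 = γ2, γ12γ1 = −γ2, γ2γ12 = −γ1, γ12γ2 = γ1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("geometric product requires finite components")
    a0, a1, a2, a12 = _comp(a)
    b0, b1, b2, b12 = _comp(b)
    out = np.empty(np.broadcast_shapes(a.shape, b.shape), dtype=float)
    out[..., 0] = a0 * b0 + a1 * b1 + a2 * b2 - a12 * b12
    out[..., 1] = a0 * b1 + a1 * b0 - a2 * b12 + a12 * b2
    out[..., 2] = a0 * b2 + a2 * b0 + a1 * b12 - a12 * b1
    out[..., 3] = a0 * b12 + a12 * b0 + a1 * b2 - a2 * b1
    return out


def reverse(a: np.ndarray) -> np.ndarray:
    """Reversion: grades 0 and 1 are fixed, the bivector part changes sign."""
    a = np.asarray(a, dtype=float)
    out = a.copy()
    out[..., 3] = -out[..., 3]
    return out


def magnitude(a: np.ndarray) -> np.ndarray:
    """Euclidean norm sqrt(e0² + e1² + e2² + e12²), per multivector."""
    a = np.asarray(a, dtype=float)
    return np.sqrt(np.sum(a * a, axis=-1))


def to_real_matrix(a: np.ndarray) -> np.ndarray:
    """The 4×4 real matrix of a multivector (right-multiplication operator).

    Satisfies ``to_real_matrix(a) @ vec(b) == vec(gp(b, a))`` and hence the
    anti-homomorphism ``M(a) M(b) = M(gp(b, a))``.
    """
    e0, e1, e2, e12 = np.asarray(a, dtype=float).reshape(4)
    return np.array(
        [
            [e0, e1, e2, -e12],
            [e1, e0, -e12, e2],
            [e2, e12, e0, -e1],
            [e12, e2, -e1, e0],
        ]
    )


def left_matrix(a: np.ndarray) -> np.ndarray:
    """The 4×4 operator of left multiplication: ``L(a) @ vec(b) == vec(gp(a, b))``."""
    e0, e1, e2, e12 = np.asarray(a, dtype=float).reshape(4)
    return np.array(
        [
            [e0, e1, e2, -e12],
            [e1, e0, e12, -e2],
            [e2, -e12, e0, e1],
            [e12, -e2, e1, e0],
        ]
    )


def vec(q: np.ndarray) -> np.ndarray:
    """Flatten an (N, 4) multivector vector to 4N reals, entry-major."""
    q = np.asarray(q, dtype=float)
    return q.reshape(-1)


def unvec(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vec`: reshape 4N reals to (N, 4)."""
    return np.asarray(x, dtype=float).reshape(-1, 4)


def real_embedding(D: np.ndarray) -> np.ndarray:
    """Embed an (N, M, 4) multivector matrix as a 4N×4M real matrix.

    Block (i, m) is ``left_matrix(D[i, m])``, so that
    ``real_embedding(D) @ vec(a) == vec(ga_matvec(D, a))``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 3 or D.shape[-1] != 4:
        raise ValueError(f"expected (N, M, 4), got {D.shape}")
    N, M, _ = D.shape
    d0, d1, d2, d12 = D[..., 0], D[..., 1], D[..., 2], D[..., 3]
    E = np.empty((N, 4, M, 4), dtype=float)
    E[:, 0, :, 0] = d0
    E[:, 0, :, 1] = d1
    E[:, 0, :, 2] = d2
    E[:, 0, :, 3] = -d12
    E[:, 1, :, 0] = d1
    E[:, 1, :, 1] = d0
    E[:, 1, :, 2] = d12
    E[:, 1, :, 3] = -d2
    E[:, 2, :, 0] = d2
    E[:, 2, :, 1] = -d12
    E[:, 2, :, 2] = d0
    E[:, 2, :, 3] = d1
    E[:, 3, :, 0] = d12
    E[:, 3, :, 1] = -d2
    E[:, 3, :, 2] = d1
    E[:, 3, :, 3] = d0
    return E.reshape(4 * N, 4 * M)


def ga_matvec(D: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Multivector matrix–vector product: entry i is Σ_m D[i,m]·a[m]."""
    D = np.asarray(D, dtype=float)
    a = np.asarray(a, dtype=float)
    if D.ndim != 3 or a.ndim != 2 or D.shape[1] != a.shape[0]:
        raise ValueError(f"shape mismatch: D {D.shape} vs a {a.shape}")
    return gp(D, a[np.newaxis, :, :]).sum(axis=1)


def ga_lstsq(D_sub: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least-squares multivector coefficients for ``q ≈ D_sub a``.

    Solved on the 4N×4k real embedding; the norm minimized is the
    root-sum-square over all 4N real components.  A rank-deficient embedded
    system yields the minimum-norm solution and is flagged in the log.
    """
    D_sub = np.asarray(D_sub, dtype=float)
    q = np.asarray(q, dtype=float)
    N, k, _ = D_sub.shape
    if 4 * N < 4 * k:
        raise ValueError(f"underdetermined system: N={N} rows for k={k} atoms")
    A = real_embedding(D_sub)
    x, _, rank, _ = np.linalg.lstsq(A, vec(q), rcond=None)
    if rank < 4 * k:
        log.warning("ga_lstsq: rank-deficient embedded system (rank %d < %d); minimum-norm solution", rank, 4 * k)
    return unvec(x)
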