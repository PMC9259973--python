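"""Independent reference implementations used only as test oracles.

Nothing here imports the package's algebra or pursuit internals: the
geometric product is re-derived by symbolic blade reduction, and the scalar
OMP / K-SVD references are classical real-valued implementations written
against the textbook algorithm descriptions.
"""

from __future__ import annotations

import numpy as np

# --- geometric product by blade reduction -----------------------------------
# Blades are tuples of generator indices; products reduce by bubble-sorting
# the generator sequence (each swap flips the sign, γi² = 1 cancels pairs).

_BLADES = [(), (1,), (2,), (1, 2)]
_BLADE_INDEX = {b: i for i, b in enumerate(_BLADES)}


def _reduce_blades(seq):
    seq = list(seq)
    sign = 1
    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(seq) - 1:
            if seq[i] == seq[i + 1]:
                del seq[i : i + 2]
                changed = True
            elif seq[i] > seq[i + 1]:
                seq[i], seq[i + 1] = seq[i + 1], seq[i]
                sign = -sign
                changed = True
            else:
                i += 1
    return sign, _BLADE_INDEX[tuple(seq)]


def gp_oracle(a, b):
    """Geometric product of two component-4 vectors by symbolic reduction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros(4)
    for i in range(4):
        for j in range(4):
            sign, k = _reduce_blades(_BLADES[i] + _BLADES[j])
            out[k] += sign * a[i] * b[j]
    return out


# --- classical scalar OMP ----------------------------------------------------


def scalar_omp(q, D, J, tol=1e-6):
    """Textbook OMP on a real dictionary with unit-norm columns.

    Selection by max |correlation| (ties → lowest index), full least-squares
    re-solve on the active set each iteration, stop at J atoms or when the
    residual norm drops below tol·‖q‖.  Returns (support list, dense coeffs).
    """
    q = np.asarray(q, dtype=float)
    D = np.asarray(D, dtype=float)
    M = D.shape[1]
    support = []
    x = np.zeros(0)
    r = q.copy()
    qn = np.linalg.norm(q)
    for _ in range(min(J, M)):
        if np.linalg.norm(r) <= tol * qn:
            break
        c = np.abs(D.T @ r)
        c[support] = -np.inf
        support.append(int(np.argmax(c)))
        Ds = D[:, support]
        x = np.linalg.lstsq(Ds, q, rcond=None)[0]
        r = q - Ds @ x
    coeffs = np.zeros(M)
    coeffs[support] = x
    return support, coeffs


# --- classical scalar K-SVD --------------------------------------------------


def _sign_fix(v):
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def scalar_ksvd(Y, M, J, iters, seed, clear_similarity=0.97, clear_min_usage=8):
    """Classical K-SVD on real data Y (N×K) with the usual housekeeping.

    Init samples M distinct nonzero data columns under the seed; each
    iteration codes with :func:`scalar_omp` (keeping the previous codes for
    any column they still fit better), updates atoms in order via the
    leading singular pair of the restricted error matrix (guarded against
    residual increase; unused atoms re-seeded from the worst-represented
    column), then re-seeds duplicate / barely-used atoms.  Returns
    (dictionary N×M, codes M×K, error history).
    """
    Y = np.asarray(Y, dtype=float)
    N, K = Y.shape
    rng = np.random.default_rng(seed)
    norms = np.linalg.norm(Y, axis=0)
    usable = np.nonzero(norms > 1e-12)[0]
    chosen = rng.choice(usable, size=M, replace=False)
    D = Y[:, chosen] / norms[chosen]

    X_prev = None
    history = []
    for it in range(iters):
        X = np.zeros((M, K))
        for j in range(K):
            _, X[:, j] = scalar_omp(Y[:, j], D, J)
        R = Y - D @ X
        if X_prev is not None:
            worse = np.einsum("ij,ij->j", R, R) > np.einsum(
                "ij,ij->j", Y - D @ X_prev, Y - D @ X_prev
            )
            X[:, worse] = X_prev[:, worse]
            R[:, worse] = (Y - D @ X_prev)[:, worse]
        for k in range(M):
            omega = np.nonzero(X[k] != 0)[0]
            if omega.size == 0:
                j = int(np.argmax(np.einsum("ij,ij->j", R, R)))
                if np.linalg.norm(Y[:, j]) > 1e-12:
                    D[:, k] = _sign_fix(Y[:, j] / np.linalg.norm(Y[:, j]))
                continue
            E = R[:, omega] + np.outer(D[:, k], X[k, omega])
            u, s, vt = np.linalg.svd(E, full_matrices=False)
            atom = _sign_fix(u[:, 0])
            row = atom @ E
            if np.sum((E - np.outer(atom, row)) ** 2) <= np.sum(
                (E - np.outer(D[:, k], X[k, omega])) ** 2
            ) + 1e-12:
                D[:, k] = atom
                X[k, omega] = row
                R[:, omega] = E - np.outer(atom, row)
        history.append(float(np.sqrt(np.mean(R**2))))
        if it < iters - 1:
            res2 = np.einsum("ij,ij->j", R, R)
            for k in range(M):
                cos = np.abs(D.T @ D[:, k])
                cos[k] = 0.0
                usage = int(np.count_nonzero(X[k]))
                if cos.max() <= clear_similarity and usage >= clear_min_usage:
                    continue
                j = int(np.argmax(res2))
                if np.linalg.norm(Y[:, j]) < 1e-12:
                    continue
                used = np.nonzero(X[k] != 0)[0]
                if used.size:
                    R[:, used] += np.outer(D[:, k], X[k, used])
                    res2[used] = np.einsum("ij,ij->j", R[:, used], R[:, used])
                    X[k, used] = 0.0
                D[:, k] = _sign_fix(Y[:, j] / np.linalg.norm(Y[:, j]))
                res2[j] = 0.0
        X_prev = X
    return D, X, history
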