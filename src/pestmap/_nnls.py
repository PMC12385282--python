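"""Exact non-negative least squares with many right-hand sides.

Both half-steps of the alternating least-squares factorisation share one
design matrix across thousands of right-hand sides (one per pixel, or one
per band).  For a small number of components k the exact NNLS solution can
be found by enumerating all 2^k candidate active sets: the optimum is the
least-squares solution on some support set, and it is the feasible
candidate with the smallest residual.  This is algebraically identical to
per-column active-set NNLS but vectorised across the right-hand sides.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.optimize

__all__ = ["nnls_multi_rhs"]

_MAX_ENUM = 10  # 2^k active sets; beyond this fall back to per-column solves


def nnls_multi_rhs(A: np.ndarray, B: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Solve ``min_X ||A X - B||_F`` subject to ``X >= 0`` columnwise.

    Parameters
    ----------
    A : ndarray, shape (m, k)
        Shared design matrix.
    B : ndarray, shape (m, n)
        Right-hand sides, one NNLS problem per column.
    ridge : float
        Optional Tikhonov term added to the normal equations, used as a
        fallback for rank-deficient subproblems.

    Returns
    -------
    X : ndarray, shape (k, n), elementwise non-negative.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, k = A.shape
    if B.shape[0] != m:
        raise ValueError(f"A has {m} rows but B has {B.shape[0]}")
    n = B.shape[1]
    if k > _MAX_ENUM:
        X = np.empty((k, n))
        for j in range(n):
            X[:, j] = scipy.optimize.nnls(A, B[:, j])[0]
        return X

    AtA = A.T @ A
    if ridge:
        AtA = AtA + ridge * np.eye(k)
    AtB = A.T @ B  # (k, n)

    best_X = np.zeros((k, n))
    # empty support: X = 0, residual ||B||^2 (constant offset dropped below,
    # so track -x.AtB which is 0 for the empty set)
    best_gain = np.zeros(n)  # gain = x^T AtB at the LS solution on the support
    tol = 1e-10 * max(1.0, float(np.abs(AtA).max()))

    for size in range(1, k + 1):
        for supp in combinations(range(k), size):
            idx = list(supp)
            sub = AtA[np.ix_(idx, idx)]
            rhs = AtB[idx, :]
            try:
                Xs = np.linalg.solve(sub, rhs)
            except np.linalg.LinAlgError:
                Xs = np.linalg.lstsq(sub + 1e-12 * np.eye(size), rhs, rcond=None)[0]
            feas = np.all(Xs >= -tol, axis=0)
            if not feas.any():
                continue
            # residual^2 = ||B||^2 - x^T AtB at the restricted LS solution
            gain = np.einsum("ij,ij->j", Xs, rhs)
            improve = feas & (gain > best_gain)
            if improve.any():
                best_gain[improve] = gain[improve]
                cols = np.where(improve)[0]
                best_X[:, cols] = 0.0
                best_X[np.ix_(idx, cols)] = np.clip(Xs[:, cols], 0.0, None)

    return best_X
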