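"""Independent reference implementations used only to cross-check results.

These deliberately share no code with the package: an SVD-based PLS1 and a
brute-force vertex (basic-feasible-solution) enumerator for small LPs.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def svd_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 via per-component SVD of the X'y cross-covariance, with deflation.

    Returns (W, P, T, q, coef) on pre-scaled data; mathematically equivalent
    to NIPALS for a single response but built from an independent code path.
    """
    Xa = X.astype(float).copy()
    ya = y.astype(float).copy()
    n, p = Xa.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        cov = (Xa.T @ ya).reshape(-1, 1)
        u_svd, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u_svd[:, 0]
        if w @ (Xa.T @ ya) < 0:  # fix the sign convention to X'y direction
            w = -w
        t = Xa @ w
        tt = float(t @ t)
        p_a = Xa.T @ t / tt
        q_a = float(ya @ t / tt)
        Xa = Xa - np.outer(t, p_a)
        ya = ya - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    coef = W @ np.linalg.solve(P.T @ W, q)
    return W, P, T, q, coef


def enumerate_lp_max(c, A_eq, lb, ub, tol=1e-9):
    """Maximize c.v s.t. A_eq v = 0, lb <= v <= ub by vertex enumeration.

    Enumerates all basic feasible solutions (choose a basis of rank columns,
    set the rest at either bound, solve) and returns (best objective, best
    vertex).  Only viable for tiny problems.
    """
    A = np.asarray(A_eq, dtype=float)
    c = np.asarray(c, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = A.shape
    r = np.linalg.matrix_rank(A)
    # reduce to r independent rows
    if r < m:
        qq, rr, piv = _qr_rows(A)
        A_red = A[piv[:r]]
    else:
        A_red = A
    best_obj, best_v = -np.inf, None
    cols = range(n)
    for basis in combinations(cols, r):
        B = A_red[:, basis]
        if abs(np.linalg.det(B)) < 1e-12:
            continue
        nonbasis = [j for j in cols if j not in basis]
        for corners in product(*[(lb[j], ub[j]) for j in nonbasis]):
            rhs = -A_red[:, nonbasis] @ np.asarray(corners)
            xb = np.linalg.solve(B, rhs)
            v = np.empty(n)
            v[list(basis)] = xb
            v[nonbasis] = corners
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                obj = float(c @ v)
                if obj > best_obj + tol:
                    best_obj, best_v = obj, v
    return best_obj, best_v


def _qr_rows(A):
    q, r, piv = np.linalg.qr(A.T), None, None
    # rank-revealing via pivoted QR on A^T columns = A rows
    from scipy.linalg import qr as sqr

    qq, rr, piv = sqr(A.T, pivoting=True)
    return qq, rr, piv
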