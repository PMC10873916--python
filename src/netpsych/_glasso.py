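"""Block coordinate-descent graphical lasso kernels (numba).

Solves, for a correlation/covariance matrix S and penalty lam,

    minimize_{K > 0}  -log det K + tr(S K) + lam * sum_{i != j} |K_ij|

with the diagonal unpenalized, via the classic covariance-updating block
coordinate descent: each column of the working covariance W is updated by
solving a lasso subproblem on the remaining block, which yields exact zeros
in the recovered precision matrix. Warm starts across a decreasing penalty
path make whole-path fits cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _cd_update(V, s, lam, beta, k):
    g = s[k]
    q = beta.shape[0]
    for m in range(q):
        if m != k:
            g -= V[k, m] * beta[m]
    old = beta[k]
    if g > lam:
        beta[k] = (g - lam) / V[k, k]
    elif g < -lam:
        beta[k] = (g + lam) / V[k, k]
    else:
        beta[k] = 0.0
    d = beta[k] - old
    return -d if d < 0.0 else d


@njit(cache=True)
def _lasso_cd(V, s, lam, beta, max_iter, tol):
    # minimize 0.5 b'Vb - s'b + lam*||b||_1 by cyclic coordinate descent,
    # full sweeps alternating with active-set sweeps
    q = beta.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(q):
            d = _cd_update(V, s, lam, beta, k)
            if d > dmax:
                dmax = d
        if dmax < tol:
            break
        # iterate on the current active set until it stabilizes
        for _ in range(max_iter):
            dmax = 0.0
            for k in range(q):
                if beta[k] == 0.0:
                    continue
                d = _cd_update(V, s, lam, beta, k)
                if d > dmax:
                    dmax = d
            if dmax < tol:
                break


@njit(cache=True)
def _glasso_cd(S, lam, W, B, max_outer, outer_tol, max_inner, inner_tol):
    """One glasso fit. W (p,p) and B (p-1,p) are warm-start state, updated
    in place. Returns (K, converged)."""
    p = S.shape[0]
    V = np.empty((p - 1, p - 1))
    s = np.empty(p - 1)
    beta = np.empty(p - 1)
    converged = False
    for _ in range(max_outer):
        dmax = 0.0
        for j in range(p):
            a = 0
            for i in range(p):
                if i == j:
                    continue
                s[a] = S[i, j]
                beta[a] = B[a, j]
                b = 0
                for m in range(p):
                    if m == j:
                        continue
                    V[a, b] = W[i, m]
                    b += 1
                a += 1
            _lasso_cd(V, s, lam, beta, max_inner, inner_tol)
            a = 0
            for i in range(p):
                if i == j:
                    continue
                w_new = 0.0
                for b in range(p - 1):
                    w_new += V[a, b] * beta[b]
                d = w_new - W[i, j]
                if d < 0.0:
                    d = -d
                if d > dmax:
                    dmax = d
                W[i, j] = w_new
                W[j, i] = w_new
                B[a, j] = beta[a]
                a += 1
        if dmax < outer_tol:
            converged = True
            break
    # recover precision from the regression coefficients
    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        a = 0
        for i in range(p):
            if i == j:
                continue
            dot += W[i, j] * B[a, j]
            a += 1
        kjj = 1.0 / (W[j, j] - dot)
        K[j, j] = kjj
        a = 0
        for i in range(p):
            if i == j:
                continue
            K[i, j] = -B[a, j] * kjj
            a += 1
    # symmetrize; exact zeros survive only when both directions agree
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 and K[j, i] == 0.0:
                continue
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, converged


@njit(cache=True)
def _glasso_path_cd(S, lambdas, max_outer, outer_tol, max_inner, inner_tol):
    """Warm-started fits along a decreasing penalty grid.

    Returns (n_lam, p, p) precision stack and a per-lambda convergence flag.
    """
    p = S.shape[0]
    n_lam = lambdas.shape[0]
    Ks = np.empty((n_lam, p, p))
    flags = np.zeros(n_lam, dtype=np.int64)
    W = S.copy()
    B = np.zeros((p - 1, p))
    for li in range(n_lam):
        K, ok = _glasso_cd(S, lambdas[li], W, B, max_outer, outer_tol,
                           max_inner, inner_tol)
        Ks[li] = K
        flags[li] = 1 if ok else 0
    return Ks, flags
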