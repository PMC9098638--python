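"""Graphical lasso inner solver, numba-compiled.

Block coordinate descent (Friedman et al. style): each sweep solves, for
every column j, the lasso problem

    min_beta  1/2 beta' W11 beta - s12' beta + lam * |beta|_1

over the remaining columns, then writes W[., j] = W11 beta back into the
working covariance.  The L1 penalty applies to off-diagonal precision
entries only, so the diagonal of W stays equal to the diagonal of S.  The
precision matrix is recovered column-wise from the final betas, which keeps
the exact zeros the soft threshold produced.

A compiled solver (instead of sklearn's ``graphical_lasso``) is used
because the permutation and bootstrap layers refit the full 100-value
regularization path tens of thousands of times; warm starts across the
descending path make the whole path cost a few sweeps per value.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _lasso_cd(V, u, beta, lam, tol, max_iter):
    """Coordinate descent for 1/2 b'Vb - u'b + lam|b|_1; updates beta in place."""
    m = u.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(m):
            g = u[k]
            for j in range(m):
                if j != k:
                    g -= V[k, j] * beta[j]
            if g > lam:
                b = (g - lam) / V[k, k]
            elif g < -lam:
                b = (g + lam) / V[k, k]
            else:
                b = 0.0
            d = abs(b - beta[k])
            if d > dmax:
                dmax = d
            beta[k] = b
        if dmax < tol:
            break
    return beta


@njit(cache=True)
def glasso(S, lam, W, B, tol, max_iter):
    """One glasso fit, warm-started from (W, B); modifies both in place.

    Parameters
    ----------
    S : (p, p) input covariance/correlation matrix.
    lam : penalty on off-diagonal precision entries.
    W : (p, p) working covariance estimate (diagonal forced to diag(S)).
    B : (p, p-1) per-column lasso coefficients from a previous fit.

    Returns
    -------
    Theta : (p, p) precision estimate (exact zeros preserved).
    converged : bool
    """
    p = S.shape[0]
    for i in range(p):
        W[i, i] = S[i, i]
    V = np.empty((p - 1, p - 1))
    u = np.empty(p - 1)
    inner_tol = tol / 10.0
    converged = False
    for _ in range(max_iter):
        dmax = 0.0
        for j in range(p):
            # V = W with row/col j removed; u = S[-j, j]
            a = 0
            for r in range(p):
                if r == j:
                    continue
                u[a] = S[r, j]
                b = 0
                for c in range(p):
                    if c == j:
                        continue
                    V[a, b] = W[r, c]
                    b += 1
                a += 1
            beta = B[j]
            _lasso_cd(V, u, beta, lam, inner_tol, 1000)
            a = 0
            for r in range(p):
                if r == j:
                    continue
                w = 0.0
                b = 0
                for c in range(p):
                    if c == j:
                        continue
                    w += V[a, b] * beta[b]
                    b += 1
                d = abs(w - W[r, j])
                if d > dmax:
                    dmax = d
                W[r, j] = w
                W[j, r] = w
                a += 1
        if dmax < tol:
            converged = True
            break
    # Recover Theta column-wise: theta_jj = 1/(w_jj - w12'beta), theta_.j = -beta*theta_jj
    Theta = np.zeros((p, p))
    for j in range(p):
        beta = B[j]
        dot = 0.0
        a = 0
        for r in range(p):
            if r == j:
                continue
            dot += W[r, j] * beta[a]
            a += 1
        tjj = 1.0 / (W[j, j] - dot)
        Theta[j, j] = tjj
        a = 0
        for r in range(p):
            if r == j:
                continue
            Theta[r, j] = -beta[a] * tjj
            a += 1
    # Symmetrize; keep exact zeros where both directions were shrunk to zero
    for i in range(p):
        for j in range(i + 1, p):
            if Theta[i, j] == 0.0 and Theta[j, i] == 0.0:
                continue
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return Theta, converged


@njit(cache=True)
def glasso_path(S, lambdas, tol, max_iter):
    """Fit glasso along a descending lambda path with warm starts.

    Returns (Thetas, logliks, converged) where logliks are the unpenalized
    Gaussian fit terms log det(Theta) - tr(S Theta).
    """
    p = S.shape[0]
    L = lambdas.shape[0]
    Thetas = np.zeros((L, p, p))
    logliks = np.full(L, -np.inf)
    converged = np.zeros(L, dtype=np.bool_)
    W = S.copy()
    B = np.zeros((p, p - 1))
    for l in range(L):
        Theta, ok = glasso(S, lambdas[l], W, B, tol, max_iter)
        Thetas[l] = Theta
        converged[l] = ok
        sign, logdet = np.linalg.slogdet(Theta)
        if sign > 0:
            tr = 0.0
            for i in range(p):
                for j in range(p):
                    tr += S[i, j] * Theta[j, i]
            logliks[l] = logdet - tr
        else:
            converged[l] = False
    return Thetas, logliks, converged
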