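"""Numba core for two-step polychoric estimation.

The observed cross-tabulation of two ordinal variables is modelled as a
discretized bivariate standard normal: cell (i, j) has probability equal to
the rectangle mass between consecutive latent thresholds.  With thresholds
fixed from the marginals (step one), the latent correlation rho is the
1-D maximum-likelihood estimate (step two), found by golden-section search
on [-1 + eps, 1 - eps].
"""

import math

import numpy as np
from numba import njit

from ._bvn import bvn_cdf

RHO_EPS = 1e-4      # distance kept from the +/-1 boundary
RHO_TOL = 1e-6      # optimizer tolerance on rho
PROB_FLOOR = 1e-12  # floor for cell probabilities in the log-likelihood

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0
_INVPHI2 = (3.0 - math.sqrt(5.0)) / 2.0


@njit(cache=True)
def pair_loglik(table, cx, cy, rho):
    """Log-likelihood sum n_ij log P_ij(rho) for one contingency table.

    ``cx``/``cy`` are latent cut arrays of length K+1 / L+1 with -inf and
    +inf sentinels at the ends, so cell (i, j) spans (cx[i], cx[i+1]] x
    (cy[j], cy[j+1]].
    """
    K = table.shape[0]
    L = table.shape[1]
    F = np.empty((K + 1, L + 1))
    for i in range(K + 1):
        for j in range(L + 1):
            F[i, j] = bvn_cdf(cx[i], cy[j], rho)
    ll = 0.0
    for i in range(K):
        for j in range(L):
            n_ij = table[i, j]
            if n_ij > 0.0:
                p = F[i + 1, j + 1] - F[i, j + 1] - F[i + 1, j] + F[i, j]
                if p < PROB_FLOOR:
                    p = PROB_FLOOR
                ll += n_ij * math.log(p)
    return ll


@njit(cache=True)
def fit_rho(table, cx, cy):
    """Golden-section ML estimate of rho on [-1+eps, 1-eps]; returns (rho, loglik)."""
    a = -1.0 + RHO_EPS
    b = 1.0 - RHO_EPS
    h = b - a
    c = a + _INVPHI2 * h
    d = a + _INVPHI * h
    fc = pair_loglik(table, cx, cy, c)
    fd = pair_loglik(table, cx, cy, d)
    while h > RHO_TOL:
        if fc > fd:
            b = d
            d = c
            fd = fc
            h = b - a
            c = a + _INVPHI2 * h
            fc = pair_loglik(table, cx, cy, c)
        else:
            a = c
            c = d
            fc = fd
            h = b - a
            d = a + _INVPHI * h
            fd = pair_loglik(table, cx, cy, d)
    rho = 0.5 * (a + b)
    return rho, pair_loglik(table, cx, cy, rho)


@njit(cache=True)
def polychoric_pairs(codes, n_cats, cuts):
    """All pairwise polychoric correlations of dense-coded ordinal columns.

    Parameters
    ----------
    codes : (n, p) int64, per-column category codes in 0..n_cats[v]-1.
    n_cats : (p,) int64 category counts.
    cuts : (p, max_cats + 1) float64; row v holds the K_v + 1 cut points
        (-inf, thresholds..., +inf) in its leading entries.

    Returns the (p, p) correlation matrix with unit diagonal.
    """
    n, p = codes.shape
    R = np.eye(p)
    for i in range(p):
        Ki = n_cats[i]
        for j in range(i + 1, p):
            Kj = n_cats[j]
            table = np.zeros((Ki, Kj))
            for t in range(n):
                table[codes[t, i], codes[t, j]] += 1.0
            rho, _ = fit_rho(table, cuts[i, : Ki + 1], cuts[j, : Kj + 1])
            R[i, j] = rho
            R[j, i] = rho
    return R
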