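"""Bivariate standard-normal CDF, numba-compiled.

Implements the Gauss–Legendre quadrature scheme of Genz (Drezner–Wesolowsky
reformulation): 6/12/20-point rules on the arcsin-transformed integral for
|rho| < 0.925 and an asymptotic expansion near |rho| = 1.  Absolute accuracy
is ~1e-15, far inside the 1e-7 target the polychoric likelihood needs.

Compiled here (rather than calling ``scipy.stats.multivariate_normal``)
because the polychoric matrix of an 8-variable dataset needs ~15k rectangle
probabilities per estimate and the bootstrap/permutation layers re-estimate
that matrix tens of thousands of times.
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_TWOPI = 2.0 * math.pi

# Gauss–Legendre nodes/weights (positive half; both signs are used).
_W6 = np.array([0.1713244923791705, 0.3607615730481384, 0.4679139345726904])
_X6 = np.array([0.9324695142031522, 0.6612093864662647, 0.2386191860831970])
_W12 = np.array([0.04717533638651177, 0.1069393259953183, 0.1600783285433464,
                 0.2031674267230659, 0.2334925365383547, 0.2491470458134029])
_X12 = np.array([0.9815606342467191, 0.9041172563704750, 0.7699026741943050,
                 0.5873179542866171, 0.3678314989981802, 0.1252334085114692])
_W20 = np.array([0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
                 0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
                 0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
                 0.1527533871307259])
_X20 = np.array([0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
                 0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
                 0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
                 0.07652652113349733])


@njit(cache=True)
def _phid(z):
    """Univariate standard-normal CDF."""
    return 0.5 * math.erfc(-z / _SQRT2)


@njit(cache=True)
def _bvnu(dh, dk, r):
    """Upper-tail probability P(X > dh, Y > dk) for corr(X, Y) = r."""
    if dh == np.inf or dk == np.inf:
        return 0.0
    if dh == -np.inf:
        return 1.0 if dk == -np.inf else _phid(-dk)
    if dk == -np.inf:
        return _phid(-dh)
    if r == 0.0:
        return _phid(-dh) * _phid(-dk)

    h = dh
    k = dk
    hk = h * k
    bvn = 0.0
    if abs(r) < 0.3:
        x, w = _X6, _W6
    elif abs(r) < 0.75:
        x, w = _X12, _W12
    else:
        x, w = _X20, _W20

    if abs(r) < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = math.asin(r) / 2.0
        for i in range(x.shape[0]):
            for s in (-1.0, 1.0):
                sn = math.sin(asr * (s * x[i] + 1.0))
                bvn += w[i] * math.exp((sn * hk - hs) / (1.0 - sn * sn))
        bvn = bvn * asr / _TWOPI + _phid(-h) * _phid(-k)
    else:
        if r < 0.0:
            k = -k
            hk = -hk
        if abs(r) < 1.0:
            ass = (1.0 - r) * (1.0 + r)
            a = math.sqrt(ass)
            bs = (h - k) * (h - k)
            c = (4.0 - hk) / 8.0
            d = (12.0 - hk) / 16.0
            asr = -(bs / ass + hk) / 2.0
            if asr > -100.0:
                bvn = (a * math.exp(asr)
                       * (1.0 - c * (bs - ass) * (1.0 - d * bs / 5.0) / 3.0
                          + c * d * ass * ass / 5.0))
            if -hk < 100.0:
                b = math.sqrt(bs)
                bvn -= (math.exp(-hk / 2.0) * math.sqrt(_TWOPI) * _phid(-b / a)
                        * b * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0))
            a /= 2.0
            for i in range(x.shape[0]):
                for s in (-1.0, 1.0):
                    xs = a * (s * x[i] + 1.0)
                    xs = xs * xs
                    rs = math.sqrt(1.0 - xs)
                    asr = -(bs / xs + hk) / 2.0
                    if asr > -100.0:
                        bvn += (a * w[i] * math.exp(asr)
                                * (math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                                   - (1.0 + c * xs * (1.0 + d * xs))))
            bvn = -bvn / _TWOPI
        if r > 0.0:
            bvn += _phid(-max(h, k))
        else:
            bvn = -bvn
            if k > h:
                bvn += _phid(k) - _phid(h)
    if bvn < 0.0:
        bvn = 0.0
    elif bvn > 1.0:
        bvn = 1.0
    return bvn


@njit(cache=True)
def bvn_cdf(x, y, r):
    """P(X <= x, Y <= y) for a standard bivariate normal with correlation r."""
    return _bvnu(-x, -y, r)
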