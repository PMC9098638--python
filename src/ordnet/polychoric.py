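"""Two-step polychoric correlation estimation.

Each ordinal variable is modelled as a thresholded standard-normal latent
variable.  Step one estimates the thresholds from the marginal category
proportions (threshold_k = Phi^-1 of the cumulative proportion up to
category k); step two maximizes, for each pair of variables, the bivariate
likelihood of the cross-tabulation over the latent correlation rho with
the thresholds held fixed.

Variables with many distinct values (more than ``max_categories``) are
treated as effectively continuous: threshold estimation becomes unstable,
so pairs involving them fall back to the Pearson correlation of the raw
values, with the fallback recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from ._polychoric import RHO_EPS, RHO_TOL, fit_rho, pair_loglik, polychoric_pairs
from .datasets import DegenerateVariableError, OrdinalDataset, dense_codes

logger = logging.getLogger("ordnet")

#: Above this number of distinct observed values a variable is treated as
#: continuous and Pearson correlation is used for its pairs.
MAX_ORDINAL_CATEGORIES = 15


@dataclass
class ThresholdSet:
    """Per-variable latent cut points on the standard-normal scale."""

    node_names: list[str]
    thresholds: list[np.ndarray]   # K_v - 1 strictly increasing values
    categories: list[np.ndarray]   # the K_v observed category labels

    def cuts(self, v: int) -> np.ndarray:
        """Thresholds of variable v padded with -inf/+inf sentinels."""
        return np.concatenate(([-np.inf], self.thresholds[v], [np.inf]))


@dataclass
class CorrelationMatrix:
    """A named correlation matrix with estimation provenance."""

    node_names: list[str]
    values: np.ndarray
    method: str = "polychoric"          # polychoric | pearson
    repaired: bool = False              # PSD repair applied
    fallback_columns: list[str] = field(default_factory=list)
    boundary_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names,
                            columns=self.node_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class PairEstimate:
    rho: float
    loglik: float
    at_boundary: bool = False


def estimate_thresholds(column) -> tuple[np.ndarray, np.ndarray]:
    """First-stage thresholds of one ordinal column.

    Returns ``(thresholds, categories)``: the K-1 cut points
    Phi^-1(cumulative proportion) and the K observed category labels
    (categories with zero count simply never appear).  A constant column
    is rejected.
    """
    x = np.asarray(column)
    cats, counts = np.unique(x, return_counts=True)
    if cats.size < 2:
        raise DegenerateVariableError(
            "degenerate variable: a single observed category")
    cum = np.cumsum(counts[:-1]) / x.size
    return ndtri(cum), cats


def estimate_polychoric_pair(table, thresholds_x, thresholds_y) -> PairEstimate:
    """Second-stage ML estimate of rho for one cross-tabulation.

    ``table`` is the complete KxL contingency table; the thresholds come
    from :func:`estimate_thresholds` on each margin.  The estimate is
    clamped to [-1+eps, 1-eps]; hitting that boundary (all mass on one
    diagonal) sets ``at_boundary``.
    """
    table = np.asarray(table, dtype=float)
    cx = np.concatenate(([-np.inf], np.asarray(thresholds_x, float), [np.inf]))
    cy = np.concatenate(([-np.inf], np.asarray(thresholds_y, float), [np.inf]))
    if table.shape != (cx.size - 1, cy.size - 1):
        raise ValueError("table shape does not match threshold counts")
    rho, ll = fit_rho(table, cx, cy)
    at_boundary = bool(abs(rho) >= 1.0 - RHO_EPS - 10 * RHO_TOL)
    if at_boundary:
        rho = float(np.sign(rho) * (1.0 - RHO_EPS))
        ll = float(pair_loglik(table, cx, cy, rho))
        logger.warning("polychoric estimate clamped at the boundary "
                       "(rho = %+.4f)", rho)
    return PairEstimate(rho=float(rho), loglik=float(ll),
                        at_boundary=at_boundary)


def _nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 0 followed by unit-diagonal rescaling."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.0, None)
    M = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(M), np.finfo(float).tiny, None))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return (M + M.T) / 2.0


def polychoric_matrix(data, max_categories: int = MAX_ORDINAL_CATEGORIES,
                      ) -> CorrelationMatrix:
    """Pairwise polychoric correlation matrix of an ordinal dataset.

    Accepts an :class:`OrdinalDataset`, DataFrame or array.  If the
    assembled matrix is not PSD it is repaired by eigenvalue clipping (the
    glasso stage requires a PSD input) and the repair is recorded.
    """
    if isinstance(data, OrdinalDataset):
        names = list(data.node_names)
        values = data.values.to_numpy()
    elif isinstance(data, pd.DataFrame):
        names = list(data.columns)
        values = data.to_numpy()
    else:
        values = np.asarray(data)
        names = [f"V{i + 1}" for i in range(values.shape[1])]
    if values.shape[1] < 2:
        raise ValueError("at least 2 variables are required")
    R, fallback, boundary = _polychoric_matrix_values(values, max_categories)
    fallback_names = [names[v] for v in fallback]
    if fallback_names:
        logger.info("Pearson fallback for high-cardinality column(s): %s",
                    ", ".join(fallback_names))
    vals = np.linalg.eigvalsh(R)
    repaired = bool(vals.min() < 0.0)
    if repaired:
        logger.warning("polychoric matrix not PSD (min eigenvalue %.3g); "
                       "repaired by eigenvalue clipping", vals.min())
        R = _nearest_psd_correlation(R)
    method = "pearson" if len(fallback) == values.shape[1] else "polychoric"
    return CorrelationMatrix(
        node_names=names, values=R, method=method, repaired=repaired,
        fallback_columns=fallback_names,
        boundary_pairs=[(names[i], names[j]) for i, j in boundary])


def _polychoric_matrix_values(values: np.ndarray, max_categories: int,
                              ) -> tuple[np.ndarray, list[int], list[tuple[int, int]]]:
    """Core assembly on a plain array; returns (R, fallback cols, boundary pairs)."""
    values = np.asarray(values)
    n, p = values.shape
    codes, n_cats, _cats = dense_codes(values)
    ordinal = np.where(n_cats <= max_categories)[0]
    fallback = [v for v in range(p) if n_cats[v] > max_categories]
    R = np.eye(p)
    if ordinal.size >= 2:
        sub = np.ascontiguousarray(codes[:, ordinal])
        sub_cats = n_cats[ordinal]
        max_k = int(sub_cats.max())
        cuts = np.full((ordinal.size, max_k + 1), np.inf)
        for a, v in enumerate(ordinal):
            k = n_cats[v]
            cum = np.bincount(codes[:, v], minlength=k).cumsum()[:-1] / n
            cuts[a, 0] = -np.inf
            cuts[a, 1:k] = ndtri(cum)
        R_sub = polychoric_pairs(sub, sub_cats, cuts)
        R[np.ix_(ordinal, ordinal)] = R_sub
    if fallback:
        C = np.corrcoef(values.astype(float).T)
        for v in fallback:
            for u in range(p):
                if u != v:
                    R[v, u] = R[u, v] = C[u, v]
    boundary = []
    iu = np.triu_indices(p, 1)
    lim = 1.0 - RHO_EPS - 10 * RHO_TOL
    for i, j in zip(*iu):
        if abs(R[i, j]) >= lim and int(i) in set(ordinal) and int(j) in set(ordinal):
            R[i, j] = R[j, i] = np.sign(R[i, j]) * (1.0 - RHO_EPS)
            boundary.append((int(i), int(j)))
    return R, fallback, boundary
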