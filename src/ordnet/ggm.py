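"""Regularized Gaussian graphical model estimation.

The estimator of the partial-correlation network: graphical lasso over a
descending log-spaced path of 100 penalty values, with the extended
Bayesian information criterion (EBIC, hyperparameter gamma) selecting one
model from the path.  The selected precision matrix Theta is converted to
edge weights via

    pcor_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj),

the partial correlation of nodes i and j controlling for all other nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glasso import glasso_path
from .polychoric import CorrelationMatrix

logger = logging.getLogger("ordnet")

#: Magnitude above which a partial correlation counts as a present edge
#: (solver zeros are exact, but symmetrization can leave dust).
EDGE_EPS = 1e-8


@dataclass
class GlassoConfig:
    """Tuning of the path-and-select estimator.

    gamma = 0.5 is the conventional EBIC setting for psychological
    networks; gamma = 0 reduces the criterion to the ordinary BIC on
    edges.  lambda_min_ratio fixes the smallest penalty as a fraction of
    lambda_max (the value at which every edge is zero).
    """

    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    gamma: float = 0.5
    tol: float = 1e-5
    max_iter: int = 200

    def __post_init__(self):
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")


@dataclass
class GlassoPath:
    """Diagnostics of the full regularization path."""

    lambdas: np.ndarray
    edge_counts: np.ndarray
    logliks: np.ndarray
    ebics: np.ndarray
    converged: np.ndarray
    selected: int
    precisions: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda": self.lambdas,
            "edges": self.edge_counts,
            "loglik": self.logliks,
            "ebic": self.ebics,
            "converged": self.converged,
            "selected": np.arange(len(self.lambdas)) == self.selected,
        })


@dataclass
class NetworkModel:
    """An estimated partial-correlation network over named nodes."""

    node_names: list[str]
    weights: np.ndarray  # symmetric, zero diagonal, entries in (-1, 1)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape[0] != w.shape[1] or w.shape[0] != len(self.node_names):
            raise ValueError("weights shape does not match node_names")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int((np.abs(self.weights[iu]) > EDGE_EPS).sum())

    def edges(self, include_zero: bool = False) -> pd.DataFrame:
        """Long-format weighted edge list (node_i, node_j, weight)."""
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                w = self.weights[i, j]
                if include_zero or abs(w) > EDGE_EPS:
                    rows.append((self.node_names[i], self.node_names[j], w))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_names,
                            columns=self.node_names)


def precision_to_partial_corr(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix (zero diagonal)."""
    theta = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def _as_corr_array(corr) -> tuple[np.ndarray, list[str]]:
    if isinstance(corr, CorrelationMatrix):
        return np.asarray(corr.values, dtype=float), list(corr.node_names)
    arr = np.asarray(corr, dtype=float)
    return arr, [f"V{i + 1}" for i in range(arr.shape[0])]


def lambda_path(corr, config: GlassoConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalty values from lambda_max down.

    lambda_max is the largest off-diagonal |correlation| — the smallest
    penalty at which the glasso solution has no edges.  An identity input
    degenerates to the single value 0 (the empty network needs no path).
    """
    config = config or GlassoConfig()
    S, _ = _as_corr_array(corr)
    p = S.shape[0]
    off = np.abs(S[np.triu_indices(p, 1)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambda)


def glasso_fit(corr, lam: float, config: GlassoConfig | None = None) -> np.ndarray:
    """Single graphical-lasso fit at one penalty value.

    Maximizes log det(Theta) - tr(S Theta) - lam * sum_{i != j} |Theta_ij|.
    """
    config = config or GlassoConfig()
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    S, _ = _as_corr_array(corr)
    W = S.copy()
    B = np.zeros((S.shape[0], S.shape[0] - 1))
    from ._glasso import glasso as _glasso_one
    theta, ok = _glasso_one(S, float(lam), W, B, config.tol, config.max_iter)
    if not ok:
        raise RuntimeError(f"glasso did not converge at lambda={lam:g}")
    return theta


def ebic(precision: np.ndarray, corr, n: int, gamma: float = 0.5) -> float:
    """EBIC = -n*(log det Theta - tr(S Theta)) + E*log n + 4*E*gamma*log p.

    E is the number of nonzero upper-triangle off-diagonal entries of the
    precision matrix; p the number of nodes.  Only differences along a
    path are meaningful.
    """
    S, _ = _as_corr_array(corr)
    theta = np.asarray(precision, dtype=float)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    p = theta.shape[0]
    iu = np.triu_indices(p, 1)
    E = int((np.abs(theta[iu]) > EDGE_EPS).sum())
    loglik = logdet - float(np.sum(S * theta))
    return float(-n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def select_network(corr, n: int, config: GlassoConfig | None = None,
                   node_names: list[str] | None = None,
                   keep_precisions: bool = True,
                   ) -> tuple[NetworkModel, GlassoPath]:
    """Fit the full path and select the minimum-EBIC network.

    Ties on EBIC are broken toward larger lambda (the sparser model).
    Returns the selected :class:`NetworkModel` and the path diagnostics.
    """
    config = config or GlassoConfig()
    S, default_names = _as_corr_array(corr)
    names = list(node_names) if node_names is not None else default_names
    p = S.shape[0]
    lambdas = lambda_path(S, config)
    if lambdas.size == 1 and lambdas[0] == 0.0:
        # identity correlation: the empty network, no path to search
        theta = np.diag(1.0 / np.diag(S))
        path = GlassoPath(lambdas=lambdas, edge_counts=np.array([0]),
                          logliks=np.array([float(np.linalg.slogdet(theta)[1] - p)]),
                          ebics=np.array([np.nan]), converged=np.array([True]),
                          selected=0, precisions=theta[None])
        net = NetworkModel(names, np.zeros((p, p)),
                           provenance={"lambda": 0.0, "gamma": config.gamma,
                                       "n": n, "degenerate": True})
        return net, path
    thetas, logliks, converged = glasso_path(S, lambdas, config.tol,
                                             config.max_iter)
    iu = np.triu_indices(p, 1)
    edge_counts = (np.abs(thetas[:, iu[0], iu[1]]) > EDGE_EPS).sum(axis=1)
    ebics = np.where(
        converged,
        -n * logliks + edge_counts * np.log(n)
        + 4.0 * config.gamma * edge_counts * np.log(p),
        np.inf)
    if not converged.any():
        raise RuntimeError("no usable model on the glasso path "
                           "(every entry failed to converge)")
    if not converged.all():
        logger.warning("glasso path: %d/%d entries did not converge and "
                       "were skipped in selection",
                       int((~converged).sum()), len(lambdas))
    selected = int(np.argmin(ebics))  # first minimum = largest lambda on ties
    weights = precision_to_partial_corr(thetas[selected])
    weights[np.abs(weights) <= EDGE_EPS] = 0.0
    net = NetworkModel(names, weights,
                       provenance={"lambda": float(lambdas[selected]),
                                   "gamma": config.gamma, "n": n})
    path = GlassoPath(lambdas=lambdas, edge_counts=edge_counts,
                      logliks=logliks, ebics=ebics, converged=converged,
                      selected=selected,
                      precisions=thetas if keep_precisions else None)
    return net, path
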