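"""Model/Results interface for ordinal partial-correlation networks.

:class:`GaussianGraphicalModel` bundles the two estimation stages — a
polychoric (or Pearson) correlation matrix, then EBIC-selected graphical
lasso — behind a statsmodels-style surface: build the model from a
DataFrame, call :meth:`~GaussianGraphicalModel.fit`, and work with the
returned :class:`GGMResults` (weights, path diagnostics, centrality,
bootstrap and stability resampling, summary table).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .datasets import OrdinalDataset
from .ggm import (GlassoConfig, GlassoPath, NetworkModel, lambda_path,
                  precision_to_partial_corr, select_network)
from .polychoric import (MAX_ORDINAL_CATEGORIES, CorrelationMatrix,
                         _nearest_psd_correlation, _polychoric_matrix_values,
                         polychoric_matrix)

CORR_METHODS = ("polychoric", "pearson")


def fit_weights(values: np.ndarray, config: GlassoConfig | None = None,
                corr_method: str = "polychoric",
                max_categories: int = MAX_ORDINAL_CATEGORIES) -> np.ndarray:
    """Fast path: data array -> selected partial-correlation weight matrix.

    Used by the bootstrap, stability and permutation layers, which refit
    the full pipeline thousands of times and only need the weights.
    """
    config = config or GlassoConfig()
    values = np.asarray(values)
    if corr_method == "pearson":
        R = np.corrcoef(values.astype(float).T)
    else:
        R, _, _ = _polychoric_matrix_values(values, max_categories)
        if np.linalg.eigvalsh(R).min() < 0.0:
            R = _nearest_psd_correlation(R)
    net, _ = select_network(R, n=values.shape[0], config=config,
                            keep_precisions=False)
    return net.weights


class GaussianGraphicalModel:
    """Regularized partial-correlation network model for ordinal data.

    Parameters
    ----------
    data : DataFrame, OrdinalDataset or array of per-subject scores
        (one column per questionnaire dimension).
    corr_method : "polychoric" (default, for ordinal scores) or "pearson".
    config : :class:`GlassoConfig` with the path/EBIC settings.
    max_categories : columns with more distinct values than this fall back
        to Pearson correlation inside the polychoric stage.
    """

    def __init__(self, data, node_names=None, corr_method: str = "polychoric",
                 config: GlassoConfig | None = None,
                 max_categories: int = MAX_ORDINAL_CATEGORIES):
        if corr_method not in CORR_METHODS:
            raise ValueError(f"corr_method must be one of {CORR_METHODS}")
        if isinstance(data, OrdinalDataset):
            self.data = data.values
            names = list(data.node_names)
        elif isinstance(data, pd.DataFrame):
            self.data = data
            names = list(data.columns)
        else:
            arr = np.asarray(data)
            names = node_names or [f"V{i + 1}" for i in range(arr.shape[1])]
            self.data = pd.DataFrame(arr, columns=names)
        if node_names is not None:
            names = list(node_names)
            self.data = self.data[names]
        if len(names) < 3:
            raise ValueError("a network needs at least 3 node columns")
        self.node_names = names
        self.corr_method = corr_method
        self.config = config or GlassoConfig()
        self.max_categories = max_categories

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, node_cols=None, **kwargs):
        return cls(df if node_cols is None else df[list(node_cols)], **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def correlation(self) -> CorrelationMatrix:
        """The first-stage correlation matrix (polychoric or Pearson)."""
        if self.corr_method == "pearson":
            R = np.corrcoef(self.data.to_numpy(dtype=float).T)
            return CorrelationMatrix(self.node_names, R, method="pearson")
        return polychoric_matrix(self.data, max_categories=self.max_categories)

    def fit(self, keep_precisions: bool = True) -> "GGMResults":
        corr = self.correlation()
        net, path = select_network(corr, n=self.nobs, config=self.config,
                                   node_names=self.node_names,
                                   keep_precisions=keep_precisions)
        net.provenance["correlation"] = corr.method
        return GGMResults(self, net, path, corr)


class GGMResults:
    """Fitted network: weights, path diagnostics, and derived quantities."""

    def __init__(self, model: GaussianGraphicalModel, network: NetworkModel,
                 path: GlassoPath, corr: CorrelationMatrix):
        self.model = model
        self.network = network
        self.path = path
        self.corr = corr
        self.node_names = network.node_names
        self.nobs = model.nobs

    @property
    def weights(self) -> pd.DataFrame:
        return self.network.to_frame()

    def edges(self, include_zero: bool = False) -> pd.DataFrame:
        return self.network.edges(include_zero=include_zero)

    @property
    def global_strength(self) -> float:
        from .nct import global_strength
        return global_strength(self.network)

    def centrality(self) -> pd.DataFrame:
        return _centrality.centrality_table(self.network)

    def bootstrap(self, B: int = 1000, seed=None):
        """Nonparametric bootstrap of edge weights and node strengths."""
        from .resampling import edge_ci_bootstrap
        return edge_ci_bootstrap(self.model.data, config=self.model.config,
                                 B=B, seed=seed,
                                 corr_method=self.model.corr_method,
                                 max_categories=self.model.max_categories,
                                 observed=self)

    def stability(self, **kwargs):
        """Case-dropping subset bootstrap of centrality stability."""
        from .resampling import case_dropping_stability
        return case_dropping_stability(self.model.data,
                                       config=self.model.config,
                                       corr_method=self.model.corr_method,
                                       observed=self, **kwargs)

    def summary(self) -> str:
        lam = self.network.provenance.get("lambda", float("nan"))
        strength = _centrality.node_strength(self.network)
        strongest = strength.idxmax()
        lines = [
            "Ordinal partial-correlation network (EBIC-glasso)",
            "=" * 49,
            f"nodes:            {len(self.node_names)}",
            f"observations:     {self.nobs}",
            f"correlation:      {self.corr.method}"
            + (" (PSD-repaired)" if self.corr.repaired else ""),
            f"path:             {len(self.path.lambdas)} lambdas, "
            f"gamma = {self.model.config.gamma}",
            f"selected lambda:  {lam:.6g}",
            f"edges selected:   {self.network.edge_count} / "
            f"{len(self.node_names) * (len(self.node_names) - 1) // 2}",
            f"global strength:  {self.global_strength:.4f}",
            f"strongest node:   {strongest} (strength {strength.max():.4f})",
            "",
            "Edges (partial correlations):",
        ]
        edges = self.edges()
        if edges.empty:
            lines.append("  (none)")
        else:
            for _, row in edges.sort_values("weight", key=abs,
                                            ascending=False).iterrows():
                lines.append(f"  {row.node_i:>4s} -- {row.node_j:<4s} "
                             f"{row.weight:+.4f}")
        return "\n".join(lines)

    def save(self, out_dir, prefix: str = "network") -> None:
        """Write the weight matrix, edge list and path diagnostics as CSV."""
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.weights.to_csv(out / f"{prefix}_weights.csv")
        self.edges(include_zero=False).to_csv(out / f"{prefix}_edges.csv",
                                              index=False)
        self.path.to_frame().to_csv(out / f"{prefix}_path.csv", index=False)
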