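"""Permutation-based network comparison between two groups (NCT).

Four families of two-sided invariance tests between independently
estimated group networks, realized through absolute-value statistics:

* structure: M = max over edges of |w1_ij - w2_ij|;
* global strength: |sum|w1|| - sum|w2||| over unordered pairs;
* individual edges: |w1_ij - w2_ij| per edge, Holm-corrected within family;
* centrality: |s1_i - s2_i| per node strength, Holm-corrected within family.

The null distribution comes from repeatedly regrouping the pooled
subjects into the original group sizes and re-running the entire
estimation pipeline (polychoric correlations + EBIC-glasso) on each
permuted split.  p-values use the add-one convention
p = (1 + #{permutation stat >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import OrdinalDataset
from .ggm import GlassoConfig, NetworkModel
from .model import fit_weights
from .polychoric import MAX_ORDINAL_CATEGORIES

logger = logging.getLogger("ordnet")


def global_strength(network) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    w = network.weights if isinstance(network, NetworkModel) else np.asarray(network)
    return float(np.abs(w[np.triu_indices(w.shape[0], 1)]).sum())


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending-sorted sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class NCTConfig:
    """Permutation-test settings (defaults: 1000 permutations, alpha 0.05)."""

    n_permutations: int = 1000
    alpha: float = 0.05
    seed: object = None
    retain_null: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class NCTResult:
    """Observed statistics, permutation p-values and Holm adjustments."""

    group_names: tuple
    node_names: list[str]
    n_permutations: int
    alpha: float
    m_observed: float                 # max absolute edge difference
    m_pvalue: float
    gs_observed: float                # |global strength difference|
    gs_pvalue: float
    global_strengths: tuple           # per-group global strengths
    edge_diffs: np.ndarray            # (p, p) absolute edge differences
    edge_pvalues: np.ndarray
    edge_holm: np.ndarray
    strength_diffs: np.ndarray        # (p,) absolute strength differences
    strength_pvalues: np.ndarray
    strength_holm: np.ndarray
    n_failed: int = 0
    null_distributions: dict | None = None
    networks: tuple = ()

    def summary_frame(self) -> pd.DataFrame:
        """Long table: one row per (family, item) with raw and Holm p."""
        rows = [("structure", "M", self.m_observed, self.m_pvalue,
                 self.m_pvalue),
                ("global_strength", "S", self.gs_observed, self.gs_pvalue,
                 self.gs_pvalue)]
        p = len(self.node_names)
        iu = np.triu_indices(p, 1)
        for i, j in zip(*iu):
            rows.append(("edge", f"{self.node_names[i]}--{self.node_names[j]}",
                         self.edge_diffs[i, j], self.edge_pvalues[i, j],
                         self.edge_holm[i, j]))
        for i, name in enumerate(self.node_names):
            rows.append(("strength", name, self.strength_diffs[i],
                         self.strength_pvalues[i], self.strength_holm[i]))
        return pd.DataFrame(rows, columns=["family", "item", "observed",
                                           "pvalue", "holm_pvalue"])

    def significant(self, family: str = "edge") -> pd.DataFrame:
        df = self.summary_frame()
        return df[(df.family == family) & (df.holm_pvalue < self.alpha)]


def _as_values(data):
    if isinstance(data, OrdinalDataset):
        return data.values.to_numpy(), list(data.node_names)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(), list(data.columns)
    arr = np.asarray(data)
    return arr, [f"V{i + 1}" for i in range(arr.shape[1])]


def _stats(w1: np.ndarray, w2: np.ndarray, iu):
    edge = np.abs(w1 - w2)[iu]
    s1 = np.abs(w1).sum(axis=1)
    s2 = np.abs(w2).sum(axis=1)
    return (edge.max(), abs(0.5 * (s1.sum() - s2.sum())), edge,
            np.abs(s1 - s2))


def compare_networks(data_group1, data_group2,
                     config: NCTConfig | None = None,
                     glasso_config: GlassoConfig | None = None,
                     corr_method: str = "polychoric",
                     max_categories: int = MAX_ORDINAL_CATEGORIES,
                     group_names=("group1", "group2")) -> NCTResult:
    """Two-group permutation network comparison test.

    Both groups must share the node set; group sizes are preserved in
    every permuted regrouping.  The permutation stream operates on a
    canonically ordered pooled sample, so swapping the two inputs leaves
    every statistic and p-value unchanged.  A permutation whose
    estimation fails is redrawn once, then counted as a failure and
    excluded; more than 5% failures raises a run-level warning.
    """
    config = config or NCTConfig()
    glasso_config = glasso_config or GlassoConfig()
    v1, names1 = _as_values(data_group1)
    v2, names2 = _as_values(data_group2)
    if names1 != names2 or v1.shape[1] != v2.shape[1]:
        raise ValueError("both groups must share the same node columns")
    names = names1
    p = v1.shape[1]
    iu = np.triu_indices(p, 1)

    def fit(vals):
        return fit_weights(vals, glasso_config, corr_method, max_categories)

    w1, w2 = fit(v1), fit(v2)
    m_obs, gs_obs, edge_obs, str_obs = _stats(w1, w2, iu)

    # Canonical pooled ordering makes the test invariant to label swap.
    pooled = np.vstack([v1, v2])
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n = pooled.shape[0]
    n_small = min(v1.shape[0], v2.shape[0])
    rng = np.random.default_rng(config.seed)

    m_ge = 0
    gs_ge = 0
    edge_ge = np.zeros(len(edge_obs), dtype=int)
    str_ge = np.zeros(p, dtype=int)
    n_ok, n_failed = 0, 0
    nulls = {"M": [], "S": []} if config.retain_null else None
    for _ in range(config.n_permutations):
        done = False
        for _attempt in range(2):  # one redraw on failure
            perm = rng.permutation(n)
            try:
                wa = fit(pooled[perm[:n_small]])
                wb = fit(pooled[perm[n_small:]])
                done = True
                break
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                logger.debug("NCT permutation failed: %s", exc)
        if not done:
            n_failed += 1
            continue
        m_p, gs_p, edge_p, str_p = _stats(wa, wb, iu)
        n_ok += 1
        m_ge += m_p >= m_obs
        gs_ge += gs_p >= gs_obs
        edge_ge += edge_p >= edge_obs
        str_ge += str_p >= str_obs
        if nulls is not None:
            nulls["M"].append(m_p)
            nulls["S"].append(gs_p)
    if n_failed > 0.05 * config.n_permutations:
        warnings.warn(f"{n_failed}/{config.n_permutations} NCT permutations "
                      "failed estimation and were excluded", RuntimeWarning)
    if n_ok == 0:
        raise RuntimeError("every NCT permutation failed estimation")

    def pval(count):
        return (1.0 + count) / (1.0 + n_ok)

    edge_pvalues = np.zeros((p, p))
    edge_pvalues[iu] = pval(edge_ge)
    edge_pvalues += edge_pvalues.T
    edge_holm = np.zeros((p, p))
    edge_holm[iu] = holm_adjust(pval(edge_ge))
    edge_holm += edge_holm.T
    edge_diffs = np.zeros((p, p))
    edge_diffs[iu] = edge_obs
    edge_diffs += edge_diffs.T
    return NCTResult(
        group_names=tuple(group_names), node_names=names,
        n_permutations=config.n_permutations, alpha=config.alpha,
        m_observed=float(m_obs), m_pvalue=float(pval(m_ge)),
        gs_observed=float(gs_obs), gs_pvalue=float(pval(gs_ge)),
        global_strengths=(global_strength(w1), global_strength(w2)),
        edge_diffs=edge_diffs, edge_pvalues=edge_pvalues, edge_holm=edge_holm,
        strength_diffs=str_obs, strength_pvalues=pval(str_ge),
        strength_holm=holm_adjust(pval(str_ge)),
        n_failed=n_failed,
        null_distributions={k: np.asarray(v) for k, v in nulls.items()}
        if nulls is not None else None,
        networks=(w1, w2))


def compare_groups_battery(dataset: OrdinalDataset,
                           config: NCTConfig | None = None,
                           glasso_config: GlassoConfig | None = None,
                           corr_method: str = "polychoric",
                           max_categories: int = MAX_ORDINAL_CATEGORIES,
                           ) -> pd.DataFrame:
    """All pairwise two-group comparisons of a multi-group dataset.

    Returns a long table with, per (group pair, family, item), the
    observed statistic, the raw permutation p-value, the Holm adjustment
    within that comparison's family, and additionally a Holm adjustment
    pooled across all pairwise comparisons of the same family (both
    corrections are reported because either correction scope is
    defensible for a multi-group battery).
    """
    config = config or NCTConfig()
    if dataset.group is None:
        raise ValueError("dataset has no group labels to compare")
    groups = dataset.group_names
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    ss = (config.seed if isinstance(config.seed, np.random.SeedSequence)
          else np.random.SeedSequence(config.seed))
    streams = ss.spawn(len(groups) * (len(groups) - 1) // 2)
    frames = []
    k = 0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            pair_cfg = NCTConfig(n_permutations=config.n_permutations,
                                 alpha=config.alpha, seed=streams[k],
                                 retain_null=config.retain_null)
            k += 1
            res = compare_networks(dataset.subset(groups[a]),
                                   dataset.subset(groups[b]),
                                   config=pair_cfg,
                                   glasso_config=glasso_config,
                                   corr_method=corr_method,
                                   max_categories=max_categories,
                                   group_names=(groups[a], groups[b]))
            df = res.summary_frame()
            df.insert(0, "group_a", str(groups[a]))
            df.insert(1, "group_b", str(groups[b]))
            df = df.rename(columns={"holm_pvalue": "holm_within_comparison"})
            frames.append(df)
    battery = pd.concat(frames, ignore_index=True)
    battery["holm_across_comparisons"] = np.nan
    for family in battery["family"].unique():
        mask = battery["family"] == family
        battery.loc[mask, "holm_across_comparisons"] = holm_adjust(
            battery.loc[mask, "pvalue"].to_numpy())
    return battery
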