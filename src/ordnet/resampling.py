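"""Bootstrap accuracy and stability diagnostics for estimated networks.

Three procedures, all of which re-run the full estimation pipeline
(polychoric correlations + EBIC-glasso selection) on resampled subjects:

* nonparametric bootstrap 95% CIs for every edge weight;
* bootstrapped difference tests between pairs of edge weights or pairs of
  node strengths (significant iff zero lies outside the percentile CI of
  the replicate-wise difference) — deliberately not corrected for
  multiple comparisons, which output headers state;
* case-dropping subset bootstrap yielding the correlation-stability (CS)
  coefficient: the largest proportion of cases that can be dropped such
  that, with 95% probability, subset-based centralities still correlate
  at least 0.7 with the full-sample ones.  CS >= 0.5 is the conventional
  "stable" verdict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import closeness_betweenness
from .datasets import OrdinalDataset
from .ggm import GlassoConfig
from .model import fit_weights
from .polychoric import MAX_ORDINAL_CATEGORIES

logger = logging.getLogger("ordnet")

DEFAULT_DROP_GRID = tuple(np.round(np.arange(1, 16) * 0.05, 2))  # 0.05 .. 0.75
CS_SENTINEL = 0.0  # "below the smallest tested proportion"


def _as_values(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, OrdinalDataset):
        return data.values.to_numpy(), list(data.node_names)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(), list(data.columns)
    arr = np.asarray(data)
    return arr, [f"V{i + 1}" for i in range(arr.shape[1])]


def _percentile_ci(samples: np.ndarray, level: float = 0.95,
                   axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Outward-rounded percentile CI (exactly min/max when B = 2)."""
    lo = (1.0 - level) / 2.0
    return (np.quantile(samples, lo, axis=axis, method="lower"),
            np.quantile(samples, 1.0 - lo, axis=axis, method="higher"))


@dataclass
class BootstrapResult:
    """Replicate-level bootstrap draws of edge weights and node strengths."""

    node_names: list[str]
    B: int
    seed: object
    weights: np.ndarray          # (B_ok, p, p) replicate weight matrices
    observed_weights: np.ndarray
    n_failed: int = 0
    level: float = 0.95

    @property
    def n_usable(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """(B_ok, p) replicate node strengths."""
        return np.abs(self.weights).sum(axis=2)

    @property
    def observed_strengths(self) -> np.ndarray:
        return np.abs(self.observed_weights).sum(axis=1)

    def edge_summary(self) -> pd.DataFrame:
        """Per-edge observed value, bootstrap mean and 95% percentile CI."""
        p = len(self.node_names)
        iu = np.triu_indices(p, 1)
        samples = self.weights[:, iu[0], iu[1]]
        lo, hi = _percentile_ci(samples, self.level)
        return pd.DataFrame({
            "node_i": [self.node_names[i] for i in iu[0]],
            "node_j": [self.node_names[j] for j in iu[1]],
            "observed": self.observed_weights[iu],
            "boot_mean": samples.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        })

    def strength_summary(self) -> pd.DataFrame:
        s = self.strengths
        lo, hi = _percentile_ci(s, self.level)
        return pd.DataFrame({
            "node": self.node_names,
            "observed": self.observed_strengths,
            "boot_mean": s.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        })


def edge_ci_bootstrap(data, config: GlassoConfig | None = None,
                      B: int = 1000, seed=None,
                      corr_method: str = "polychoric",
                      max_categories: int = MAX_ORDINAL_CATEGORIES,
                      observed=None) -> BootstrapResult:
    """Nonparametric bootstrap of the whole estimation pipeline.

    Each replicate resamples subjects with replacement and re-runs
    polychoric estimation and EBIC-glasso selection.  Replicates whose
    estimation fails (e.g. a resampled column going constant) are logged
    and excluded; more than 10% failures raises a run-level warning.
    """
    config = config or GlassoConfig()
    values, names = _as_values(data)
    n, p = values.shape
    if observed is not None:
        obs_w = observed.network.weights
    else:
        obs_w = fit_weights(values, config, corr_method, max_categories)
    rng = np.random.default_rng(seed)
    reps, n_failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            reps.append(fit_weights(values[idx], config, corr_method,
                                    max_categories))
        except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if n_failed > 0.1 * B:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed "
                      "estimation and were excluded", RuntimeWarning)
    if not reps:
        raise RuntimeError("every bootstrap replicate failed estimation")
    return BootstrapResult(node_names=names, B=B, seed=seed,
                           weights=np.stack(reps), observed_weights=obs_w,
                           n_failed=n_failed)


@dataclass
class DifferenceTestResult:
    """Pairwise bootstrapped difference tests (no multiplicity correction)."""

    target: str                   # "edges" or "strength"
    labels: list[str]
    observed: np.ndarray
    pairs: pd.DataFrame           # item_a, item_b, diff CI, significant
    greater_counts: pd.Series     # times each item significantly exceeds others
    level: float = 0.95
    _samples: np.ndarray = field(default=None, repr=False)

    def pair_difference(self, label_a: str, label_b: str):
        """CI and verdict for one (possibly identical) pair of items."""
        ia, ib = self.labels.index(label_a), self.labels.index(label_b)
        d = self._samples[:, ia] - self._samples[:, ib]
        lo, hi = _percentile_ci(d, self.level)
        return float(d.mean()), float(lo), float(hi), bool(lo > 0 or hi < 0)


def difference_tests(bootstrap: BootstrapResult, targets: str = "edges",
                     level: float = 0.95) -> DifferenceTestResult:
    """Bootstrapped difference tests between edges or node strengths.

    For every unordered pair of items the 95% percentile CI of the
    replicate-wise difference is formed; a pair differs significantly iff
    zero lies outside that CI.  Also tallies, per item, how often it is
    significantly greater than the other items (the tabular counterpart
    of the usual tile plots).  Intentionally uncorrected for multiple
    comparisons.
    """
    if bootstrap.n_usable < 100:
        raise ValueError(
            f"only {bootstrap.n_usable} usable bootstrap replicates; "
            "at least 100 are required for difference tests")
    names = bootstrap.node_names
    if targets == "edges":
        p = len(names)
        iu = np.triu_indices(p, 1)
        labels = [f"{names[i]}--{names[j]}" for i, j in zip(*iu)]
        samples = bootstrap.weights[:, iu[0], iu[1]]
        observed = bootstrap.observed_weights[iu]
    elif targets == "strength":
        labels = list(names)
        samples = bootstrap.strengths
        observed = bootstrap.observed_strengths
    else:
        raise ValueError("targets must be 'edges' or 'strength'")
    m = len(labels)
    rows = []
    greater = np.zeros(m, dtype=int)
    for a in range(m):
        for b in range(a + 1, m):
            d = samples[:, a] - samples[:, b]
            lo, hi = _percentile_ci(d, level)
            sig = bool(lo > 0 or hi < 0)
            if sig:
                greater[a if d.mean() > 0 else b] += 1
            rows.append((labels[a], labels[b], float(d.mean()),
                         float(lo), float(hi), sig))
    pairs = pd.DataFrame(rows, columns=["item_a", "item_b", "mean_diff",
                                        "ci_lower", "ci_upper", "significant"])
    return DifferenceTestResult(
        target=targets, labels=labels, observed=np.asarray(observed),
        pairs=pairs,
        greater_counts=pd.Series(greater, index=labels,
                                 name="times_significantly_greater"),
        level=level, _samples=samples)


@dataclass
class StabilityResult:
    """Case-dropping subset bootstrap of centrality stability."""

    node_names: list[str]
    grid: np.ndarray                  # drop proportions actually tested
    skipped: list[float]              # proportions skipped (subset too small)
    correlations: dict                # index -> (len(grid), B) array, NaN = failure
    B: int
    seed: object
    cor_threshold: float = 0.7
    probability: float = 0.95
    stable_cutoff: float = 0.5

    def retention_fractions(self, index: str,
                            cor_threshold: float | None = None) -> np.ndarray:
        thr = self.cor_threshold if cor_threshold is None else cor_threshold
        arr = self.correlations[index]
        with np.errstate(invalid="ignore"):
            ok = arr >= thr  # NaN (failed subset fit) counts against
        return ok.mean(axis=1)

    def cs_for(self, index: str, cor_threshold: float | None = None,
               probability: float | None = None) -> float:
        """CS coefficient under an arbitrary (threshold, probability) rule."""
        prob = self.probability if probability is None else probability
        frac = self.retention_fractions(index, cor_threshold)
        ok = frac >= prob
        return float(self.grid[ok].max()) if ok.any() else CS_SENTINEL

    @property
    def cs(self) -> dict:
        return {idx: self.cs_for(idx) for idx in self.correlations}

    @property
    def verdicts(self) -> dict:
        """'stable' iff at least ``stable_cutoff`` of cases can be dropped."""
        return {idx: ("stable" if v >= self.stable_cutoff else "unstable")
                for idx, v in self.cs.items()}

    def curve_frame(self) -> pd.DataFrame:
        rows = []
        for idx in self.correlations:
            frac = self.retention_fractions(idx)
            for prop, f in zip(self.grid, frac):
                rows.append((idx, float(prop), float(f)))
        return pd.DataFrame(rows, columns=["index", "drop_proportion",
                                           f"share_cor_ge_{self.cor_threshold}"])

    def to_dict(self) -> dict:
        return {"cs": self.cs, "verdicts": self.verdicts,
                "cor_threshold": self.cor_threshold,
                "probability": self.probability,
                "stable_cutoff": self.stable_cutoff,
                "skipped_proportions": [float(s) for s in self.skipped],
                "B": self.B}


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0 or not (np.isfinite(x).all()
                                                and np.isfinite(y).all()):
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def case_dropping_stability(data, config: GlassoConfig | None = None,
                            grid=DEFAULT_DROP_GRID, B: int = 1000, seed=None,
                            indices=("strength", "closeness", "betweenness"),
                            cor_threshold: float = 0.7,
                            probability: float = 0.95,
                            stable_cutoff: float = 0.5,
                            corr_method: str = "polychoric",
                            max_categories: int = MAX_ORDINAL_CATEGORIES,
                            observed=None) -> StabilityResult:
    """Case-dropping subset bootstrap (CS coefficient) per centrality index.

    For every drop proportion in ``grid``, ``B`` subsets of the data are
    drawn without replacement, the pipeline is re-run on each, and the
    Pearson correlation (over nodes) between subset and full-sample
    centralities is recorded.  Subset fits that fail, or correlations
    undefined because a side has zero variance, count against the
    probability criterion.  Proportions leaving fewer than 3x(number of
    nodes) subjects are skipped with a notice.
    """
    config = config or GlassoConfig()
    values, names = _as_values(data)
    n, p = values.shape
    if observed is not None:
        full_w = observed.network.weights
    else:
        full_w = fit_weights(values, config, corr_method, max_categories)
    full = _centrality_vectors(full_w, indices, names)
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(grid), dtype=float)
    tested, skipped = [], []
    corrs = {idx: [] for idx in indices}
    for prop in grid:
        m = int(round(n * (1.0 - prop)))
        if m < 3 * p:
            skipped.append(float(prop))
            logger.info("stability: drop proportion %.2f skipped "
                        "(subset size %d < %d)", prop, m, 3 * p)
            continue
        tested.append(float(prop))
        row = {idx: np.full(B, np.nan) for idx in indices}
        for b in range(B):
            sub = rng.choice(n, size=m, replace=False)
            try:
                w = fit_weights(values[sub], config, corr_method,
                                max_categories)
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                continue  # stays NaN -> counted as failure
            sub_cent = _centrality_vectors(w, indices, names)
            for idx in indices:
                row[idx][b] = _pearson_or_nan(full[idx], sub_cent[idx])
        for idx in indices:
            corrs[idx].append(row[idx])
    return StabilityResult(
        node_names=names, grid=np.asarray(tested), skipped=skipped,
        correlations={idx: np.vstack(arrs) if arrs else np.empty((0, B))
                      for idx, arrs in corrs.items()},
        B=B, seed=seed, cor_threshold=cor_threshold, probability=probability,
        stable_cutoff=stable_cutoff)


def _centrality_vectors(weights: np.ndarray, indices, names) -> dict:
    out = {}
    if "strength" in indices:
        out["strength"] = np.abs(weights).sum(axis=1)
    if "closeness" in indices or "betweenness" in indices:
        cb = closeness_betweenness(weights, names)
        for idx in ("closeness", "betweenness"):
            if idx in indices:
                out[idx] = cb[idx].to_numpy(dtype=float)
    return out
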