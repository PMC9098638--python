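"""Synthetic grouped ordinal data from known sparse latent networks.

The generator is the exact inverse of the analysis model: a sparse
precision matrix defines a latent multivariate normal; latent draws are
thresholded into ordinal categories.  Every downstream stage (polychoric
estimation, EBIC-glasso selection, centrality, bootstrap, permutation
comparison) therefore has ground truth to be checked against.

Groups emulate a multi-cohort design (e.g. diagnosis groups): each group
either shares the base generating network (null) or perturbs named edges
(alternative).  Group draws come from independently spawned substreams of
one seed, so adding a group never changes earlier groups' data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .datasets import SQOL18_DIMENSIONS, OrdinalDataset
from .ggm import precision_to_partial_corr

logger = logging.getLogger("ordnet")

STRUCTURES = ("chain", "hub", "random-sparse", "explicit")


@dataclass
class TruePrecisionSpec:
    """A target sparse precision matrix with uniform edge partial correlations.

    ``structure`` picks the zero pattern: "chain" links consecutive nodes,
    "hub" links node 0 to all others, "random-sparse" draws each of the
    p(p-1)/2 possible edges with probability ``edge_density``, and
    "explicit" takes ``explicit_matrix`` as given (must be symmetric
    positive definite).  ``partial_cor_value`` is the partial correlation
    every structural edge is calibrated to.
    """

    node_names: list[str] = field(default_factory=lambda: list(SQOL18_DIMENSIONS))
    structure: str = "chain"
    partial_cor_value: float = 0.3
    edge_density: float | None = None
    explicit_matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if not -1.0 < self.partial_cor_value < 1.0:
            raise ValueError("partial_cor_value must be in (-1, 1)")
        if self.structure == "random-sparse" and self.edge_density is None:
            raise ValueError("random-sparse structure requires edge_density")


@dataclass
class DiscretizationSpec:
    """How latent normals become observed ordinal scores.

    Default: 5 response categories cut at equiprobable standard-normal
    quantiles.  ``thresholds`` overrides the cut points per variable;
    ``score_mapping = (offset, step)`` affinely maps category index k to
    ``offset + step * k`` (e.g. ``percent_mapping(5) -> (0, 25)`` for a
    0-100 score grid).
    """

    n_categories: int = 5
    thresholds: list[np.ndarray] | None = None
    score_mapping: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.thresholds is not None:
            for t in self.thresholds:
                t = np.asarray(t, dtype=float)
                if t.size != self.n_categories - 1:
                    raise ValueError("need n_categories - 1 thresholds per variable")
                if not np.all(np.diff(t) > 0) or not np.all(np.isfinite(t)):
                    raise ValueError("thresholds must be finite and strictly increasing")

    def cut_points(self, n_vars: int) -> list[np.ndarray]:
        if self.thresholds is not None:
            return [np.asarray(t, dtype=float) for t in self.thresholds]
        k = self.n_categories
        equi = ndtri(np.arange(1, k) / k)
        return [equi.copy() for _ in range(n_vars)]


def percent_mapping(n_categories: int) -> tuple[float, float]:
    """Affine score map putting categories on the 0-100 grid."""
    return (0.0, 100.0 / (n_categories - 1))


@dataclass
class EdgeChange:
    """One edge modification: set a new partial correlation or rescale.

    ``pcor`` sets the edge's partial correlation (0 removes the edge);
    ``scale`` multiplies the precision entry instead.  Exactly one of the
    two must be given.
    """

    node_a: str
    node_b: str
    pcor: float | None = None
    scale: float | None = None

    def __post_init__(self):
        if (self.pcor is None) == (self.scale is None):
            raise ValueError("give exactly one of pcor or scale")


@dataclass
class GroupDesign:
    """Group names, sizes and optional per-group edge perturbations."""

    group_names: list[str]
    group_sizes: list[int]
    perturbations: dict[str, list[EdgeChange]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("group_names and group_sizes differ in length")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 subjects")
        unknown = set(self.perturbations) - set(self.group_names)
        if unknown:
            raise ValueError(f"perturbations for unknown group(s): {sorted(unknown)}")

    @classmethod
    def single(cls, n: int, name: str = "all") -> "GroupDesign":
        return cls(group_names=[name], group_sizes=[n])


def _adjacency(spec: TruePrecisionSpec, rng: np.random.Generator | None,
               ) -> np.ndarray:
    p = len(spec.node_names)
    A = np.zeros((p, p), dtype=bool)
    if spec.structure == "chain":
        for i in range(p - 1):
            A[i, i + 1] = A[i + 1, i] = True
    elif spec.structure == "hub":
        A[0, 1:] = A[1:, 0] = True
    elif spec.structure == "random-sparse":
        rng = rng if rng is not None else np.random.default_rng()
        for i in range(p):
            for j in range(i + 1, p):
                if rng.random() < spec.edge_density:
                    A[i, j] = A[j, i] = True
    return A


def build_precision(spec: TruePrecisionSpec,
                    rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Symmetric positive-definite precision matrix realizing the spec.

    For structural patterns the off-diagonals are calibrated so that every
    present edge has partial correlation exactly ``partial_cor_value``
    (within 1e-6) and every absent edge exactly 0.  Positive definiteness
    is enforced by a ridge shift (delta = -lambda_min + 0.05) followed by
    re-calibration, iterated at most 50 times; an infeasible target (too
    strong for the pattern) raises.
    """
    p = len(spec.node_names)
    if spec.structure == "explicit":
        M = np.asarray(spec.explicit_matrix, dtype=float)
        if M.shape != (p, p):
            raise ValueError("explicit_matrix shape does not match node_names")
        if not np.allclose(M, M.T):
            raise ValueError("explicit_matrix must be symmetric")
        lmin = float(np.linalg.eigvalsh(M).min())
        if lmin <= 0.0:
            raise ValueError(
                f"explicit_matrix is not positive definite "
                f"(smallest eigenvalue {lmin:.6g})")
        return M.copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    A = _adjacency(spec, rng)
    r = spec.partial_cor_value
    theta = np.eye(p)
    theta[A] = -r
    for _ in range(50):
        d = np.sqrt(np.diag(theta))
        off = -r * np.outer(d, d)
        theta = np.diag(np.diag(theta)).astype(float)
        theta[A] = off[A]
        lmin = float(np.linalg.eigvalsh(theta).min())
        if lmin <= 1e-8:
            theta[np.diag_indices(p)] += -lmin + 0.05
            continue
        pcor = precision_to_partial_corr(theta)
        err = np.abs(pcor[A] - r).max() if A.any() else 0.0
        if err < 1e-6:
            return theta
    raise ValueError(
        f"could not calibrate a positive-definite precision matrix with "
        f"partial correlation {r} on a {spec.structure!r} pattern "
        f"(target likely infeasible)")


def apply_perturbation(precision: np.ndarray, changes: list[EdgeChange],
                       node_names: list[str]) -> np.ndarray:
    """Perturbed copy of a precision matrix; rejects a non-PD result."""
    theta = np.asarray(precision, dtype=float).copy()
    index = {name: i for i, name in enumerate(node_names)}
    for ch in changes:
        i, j = index[ch.node_a], index[ch.node_b]
        if ch.pcor is not None:
            v = -ch.pcor * np.sqrt(theta[i, i] * theta[j, j])
        else:
            v = theta[i, j] * ch.scale
        theta[i, j] = theta[j, i] = v
    lmin = float(np.linalg.eigvalsh(theta).min())
    if lmin <= 0.0:
        raise ValueError(
            f"perturbed precision matrix is not positive definite "
            f"(smallest eigenvalue {lmin:.6g})")
    return theta


def latent_correlation(precision: np.ndarray) -> np.ndarray:
    """Latent correlation matrix: inverse precision rescaled to unit diagonal."""
    sigma = np.linalg.inv(np.asarray(precision, dtype=float))
    d = np.sqrt(np.diag(sigma))
    R = sigma / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def sample_ordinal(precision: np.ndarray, disc: DiscretizationSpec,
                   design: GroupDesign, seed,
                   node_names: list[str] | None = None,
                   return_latent: bool = False):
    """Draw a grouped ordinal dataset from the latent-network model.

    Each group's latent draws are N(0, R_g) with R_g the unit-diagonal
    rescaled inverse of that group's (possibly perturbed) precision
    matrix; observed categories are the thresholded latents, optionally
    mapped onto a score grid.  Substreams are spawned per group from the
    one seed, in group order.
    """
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    names = list(node_names) if node_names is not None else [f"V{i+1}" for i in range(p)]
    if len(names) != p:
        raise ValueError("node_names length does not match precision size")
    cuts = disc.cut_points(p)
    streams = np.random.SeedSequence(seed).spawn(len(design.group_names))
    blocks, labels, latents = [], [], []
    for g, (gname, gsize) in enumerate(zip(design.group_names, design.group_sizes)):
        theta_g = apply_perturbation(precision, design.perturbations.get(gname, []),
                                     names)
        R = latent_correlation(theta_g)
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(streams[g])
        Z = rng.standard_normal((gsize, p)) @ L.T
        codes = np.empty((gsize, p), dtype=np.int64)
        for v in range(p):
            codes[:, v] = np.searchsorted(cuts[v], Z[:, v])
        blocks.append(codes)
        labels.extend([gname] * gsize)
        if return_latent:
            latents.append(Z)
    codes = np.vstack(blocks)
    if disc.score_mapping is not None:
        offset, step = disc.score_mapping
        values = offset + step * codes.astype(float)
    else:
        values = codes
    df = pd.DataFrame(values, columns=names)
    ds = OrdinalDataset(df, group=pd.Series(labels, name="group"),
                        node_names=names)
    if return_latent:
        return ds, np.vstack(latents)
    return ds


def simulate_study(spec: TruePrecisionSpec, disc: DiscretizationSpec,
                   design: GroupDesign, seed,
                   rng_structure: np.random.Generator | int | None = None,
                   ) -> tuple[OrdinalDataset, np.ndarray]:
    """Convenience wrapper: build the precision, then sample the dataset.

    Returns ``(dataset, precision)`` so callers keep the ground truth.
    """
    theta = build_precision(spec, rng=rng_structure)
    ds = sample_ordinal(theta, disc, design, seed, node_names=spec.node_names)
    return ds, theta


def ground_truth_sidecar(precision: np.ndarray, disc: DiscretizationSpec,
                         design: GroupDesign, seed,
                         node_names: list[str]) -> dict:
    """JSON-serializable record of the generating model for a written dataset."""
    cuts = disc.cut_points(len(node_names))
    per_group = {}
    for gname in design.group_names:
        theta_g = apply_perturbation(precision, design.perturbations.get(gname, []),
                                     node_names)
        per_group[str(gname)] = np.asarray(theta_g).tolist()
    return {
        "node_names": list(node_names),
        "seed": int(seed),
        "precision": np.asarray(precision).tolist(),
        "group_precisions": per_group,
        "thresholds": [c.tolist() for c in cuts],
        "group_sizes": {str(g): int(n) for g, n in
                        zip(design.group_names, design.group_sizes)},
        "score_mapping": list(disc.score_mapping) if disc.score_mapping else None,
    }
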