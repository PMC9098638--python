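"""Containers and I/O for grouped ordinal questionnaire data.

The canonical analysis input is one row per subject, one numeric column per
questionnaire dimension (ordinal category codes or mapped 0-100 scores),
plus an optional categorical group column (e.g. diagnosis group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The eight S-QoL18 quality-of-life dimensions: self-esteem, romantic
#: life, resilience, psychological well-being, physical well-being,
#: friendships, family relationships, autonomy.
SQOL18_DIMENSIONS = ["SEL", "ROM", "RES", "PSY", "PHY", "FRI", "FAM", "AUT"]

GROUP_COLUMN = "group"


class DegenerateVariableError(ValueError):
    """A variable is constant (or otherwise unusable) for estimation."""


@dataclass
class OrdinalDataset:
    """Subjects x ordinal variables, with optional per-subject group labels.

    ``values`` holds numeric codes/scores (no missing values — missingness
    is resolved by the reader); ``group`` is aligned with the rows of
    ``values`` or ``None`` for a single undifferentiated sample.
    """

    values: pd.DataFrame
    group: pd.Series | None = None
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = self.values.reset_index(drop=True)
        if not self.node_names:
            self.node_names = list(self.values.columns)
        else:
            self.values = self.values[self.node_names]
        if self.values.isna().any().any():
            raise ValueError("OrdinalDataset does not accept missing values")
        for col in self.node_names:
            if not np.issubdtype(self.values[col].dtype, np.number):
                raise ValueError(f"node column {col!r} is not numeric")
        if self.group is not None:
            self.group = pd.Series(np.asarray(self.group), name=GROUP_COLUMN)
            if len(self.group) != len(self.values):
                raise ValueError("group labels and values have different lengths")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def group_names(self) -> list:
        if self.group is None:
            return []
        return list(pd.unique(self.group))

    def subset(self, group_name) -> "OrdinalDataset":
        """The single-group dataset for one group level."""
        if self.group is None:
            raise ValueError("dataset has no group labels")
        mask = (self.group == group_name).to_numpy()
        if not mask.any():
            raise KeyError(f"no subjects in group {group_name!r}")
        return OrdinalDataset(self.values.loc[mask].reset_index(drop=True),
                              node_names=list(self.node_names))

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        if self.group is not None:
            df[GROUP_COLUMN] = self.group.to_numpy()
        return df

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        """Write subjects as CSV; optionally a JSON sidecar with ground truth.

        The sidecar (written next to the CSV as ``<name>.meta.json``)
        records whatever generating information is supplied — typically the
        true precision matrices, thresholds and the seed.
        """
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            side = path.with_suffix(path.suffix + ".meta.json")
            side.write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, node_names=None,
                   group_col=GROUP_COLUMN) -> "OrdinalDataset":
        group = None
        if group_col is not None and group_col in df.columns:
            group = df[group_col]
        if node_names is None:
            node_names = [c for c in df.columns if c != group_col]
        return cls(df[list(node_names)].copy(), group=group,
                   node_names=list(node_names))

    @classmethod
    def read_csv(cls, path, node_names=None, group_col=GROUP_COLUMN) -> "OrdinalDataset":
        return cls.from_frame(pd.read_csv(path), node_names=node_names,
                              group_col=group_col)


def dense_codes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Re-index each column to dense 0..K-1 category codes.

    Returns ``(codes, n_categories, category_values)`` where
    ``category_values[v]`` maps code -> original value for column v.
    Raises :class:`DegenerateVariableError` listing every constant column.
    """
    values = np.asarray(values)
    n, p = values.shape
    codes = np.empty((n, p), dtype=np.int64)
    n_cats = np.empty(p, dtype=np.int64)
    cats = []
    degenerate = []
    for v in range(p):
        uniq, inv = np.unique(values[:, v], return_inverse=True)
        codes[:, v] = inv
        n_cats[v] = uniq.size
        cats.append(uniq)
        if uniq.size < 2:
            degenerate.append(v)
    if degenerate:
        raise DegenerateVariableError(
            f"degenerate variable(s) with a single observed category at "
            f"column index(es) {degenerate}")
    return codes, n_cats, cats
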