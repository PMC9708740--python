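"""Core in-memory containers shared by every pipeline stage.

All tabular data is held in :class:`pandas.DataFrame` / :class:`pandas.Series`
objects; the thin dataclass wrappers exist to enforce the invariants every
downstream stage assumes (unique identifiers, finite values, complete biotype
annotation) at construction time rather than deep inside an analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

VALID_BIOTYPES = ("lncRNA", "protein_coding", "other")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, features in rows, samples in columns.

    Parameters
    ----------
    values
        Numeric frame indexed by feature id with sample ids as columns.
    biotype
        Series mapping every feature id to one of ``lncRNA``,
        ``protein_coding`` or ``other``. Features missing from the mapping
        are labelled ``other``.
    """

    values: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy()).all():
            r, c = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValueError(
                f"non-finite expression value at feature "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        bt = pd.Series(self.biotype, dtype=object)
        bt = bt.reindex(self.values.index).fillna("other")
        bt.index.name = None
        bt.name = None
        bad = set(bt.unique()) - set(VALID_BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotype label(s): {sorted(bad)}")
        self.biotype = bt

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_biotype(self, biotype: str) -> "ExpressionMatrix":
        """Restrict to features of one biotype (e.g. ``lncRNA``)."""
        keep = self.biotype[self.biotype == biotype].index
        return ExpressionMatrix(self.values.loc[keep], self.biotype.loc[keep])

    def subset_features(self, features) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise KeyError(f"features absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(features)], self.biotype.loc[list(features)]
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.biotype)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival records.

    ``os_time`` in days (non-negative), ``os_event`` 0 = alive/censored,
    1 = dead. ``stage`` and any further covariate columns are carried along
    untouched.
    """

    table: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample")
        for col in ("os_time", "os_event"):
            if col not in t.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        t = t.copy()
        t["os_time"] = t["os_time"].astype(float)
        t["os_event"] = t["os_event"].astype(int)
        if (t["os_time"] < 0).any():
            bad = t.index[t["os_time"] < 0][0]
            raise ValueError(f"negative os_time for sample {bad!r}")
        if not t["os_event"].isin([0, 1]).all():
            bad = t.index[~t["os_event"].isin([0, 1])][0]
            raise ValueError(f"os_event not in {{0,1}} for sample {bad!r}")
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def os_time(self) -> pd.Series:
        return self.table["os_time"]

    @property
    def os_event(self) -> pd.Series:
        return self.table["os_event"]

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(samples)])


@dataclass
class GeneSetCollection:
    """Named gene sets (hallmark EMT, immune-cell signatures, ...)."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("no gene sets")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicates")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and clustering parameters.

    Defaults are the screen thresholds (|r| > 0.25, p < 0.05), FDR < 0.05,
    consensus clustering with 500 bootstraps of 80% of samples over
    k = 2..10, and ssGSEA rank-weight exponent 0.25.
    """

    seed: int = 0
    r_thresh: float = 0.25
    p_thresh: float = 0.05
    fdr_thresh: float = 0.05
    k_min: int = 2
    k_max: int = 10
    n_boot: int = 500
    subsample: float = 0.8
    ssgsea_alpha: float = 0.25
    out_dir: str = "lncemt_out"

    def __post_init__(self) -> None:
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must lie in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        for name in ("r_thresh", "p_thresh", "fdr_thresh"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RegulonTable:
    """Signed TF -> target edges; ``mode`` is +1 (activation) or -1."""

    table: pd.DataFrame  # columns tf, target, mode

    def __post_init__(self) -> None:
        t = self.table
        for col in ("tf", "target", "mode"):
            if col not in t.columns:
                raise ValueError(f"regulon table lacks column {col!r}")
        t = t.copy()
        t["mode"] = t["mode"].astype(int)
        if not t["mode"].isin([1, -1]).all():
            bad = t.loc[~t["mode"].isin([1, -1])].iloc[0]
            raise ValueError(
                f"regulon mode must be +1 or -1, got {bad['mode']} "
                f"for edge {bad['tf']}->{bad['target']}"
            )
        if t.duplicated(["tf", "target"]).any():
            bad = t.loc[t.duplicated(["tf", "target"])].iloc[0]
            raise ValueError(f"duplicate regulon edge {bad['tf']}->{bad['target']}")
        self.table = t

    def tfs(self) -> list[str]:
        return list(self.table["tf"].unique())

    def targets_of(self, tf: str) -> pd.DataFrame:
        return self.table.loc[self.table["tf"] == tf, ["target", "mode"]]
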