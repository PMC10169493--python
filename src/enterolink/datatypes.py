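"""Shared domain containers for the pipeline.

All tabular containers wrap a :class:`pandas.DataFrame` with samples as rows
and features (genera, metabolites, modules, phenotype variables) as columns.
The wrappers add validation (unique ids, closure of proportions, symmetry of
distance matrices) and a uniform ``to_frame`` / serialization surface.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "OmicsMatrix",
    "PhenotypeTable",
    "DistanceMatrix",
    "DifferentialTable",
    "ValidationError",
]

LAYER_TAGS = ("rumen_micro", "rumen_metab", "serum_metab", "milk_metab", "module_scores")


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} id(s): {sorted(set(dups))}")


def _check_numeric(df: pd.DataFrame) -> None:
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValidationError(f"non-numeric column(s): {bad}")


@dataclass
class AbundanceTable:
    """Samples x taxa relative-abundance table; rows are renormalized to sum 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        _check_numeric(df)
        if df.empty:
            raise ValidationError("empty abundance table")
        vals = df.to_numpy()
        if np.any(vals < 0):
            raise ValidationError("negative abundance entries")
        row_sums = vals.sum(axis=1)
        if np.any(row_sums <= 0):
            bad = list(df.index[row_sums <= 0])
            raise ValidationError(f"sample(s) with zero total abundance: {bad}")
        if np.any(np.abs(row_sums - 1.0) > 1e-6):
            warnings.warn(
                "abundance rows do not sum to 1; renormalizing to proportions",
                UserWarning,
                stacklevel=2,
            )
        self.data = df.div(row_sums, axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def restrict(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)])


@dataclass
class OmicsMatrix:
    """Samples x features real-valued matrix for one omics layer."""

    data: pd.DataFrame
    layer_tag: str = "rumen_metab"

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "feature")
        _check_numeric(df)
        if df.empty:
            raise ValidationError("empty omics matrix")
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}; expected one of {LAYER_TAGS}")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def restrict(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(sample_ids)], self.layer_tag)


@dataclass
class PhenotypeTable:
    """Per-sample phenotype variables (MPY, milk yield, VFAs, serum chemistry).

    ``group_label`` optionally carries an enterotype assignment per sample.
    """

    data: pd.DataFrame
    group_label: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "variable")
        if df.empty:
            raise ValidationError("empty phenotype table")
        if "MPY" in df.columns and np.any(df["MPY"].to_numpy() < 0):
            raise ValidationError("negative MPY")
        if self.group_label is not None:
            self.group_label = pd.Series(self.group_label).reindex(df.index)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def restrict(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        g = None if self.group_label is None else self.group_label.loc[list(sample_ids)]
        return PhenotypeTable(self.data.loc[list(sample_ids)], g)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distances."""

    data: pd.DataFrame
    metric_tag: str = "unknown"

    def __post_init__(self) -> None:
        df = self.data.astype(float)
        _check_unique(df.index, "sample")
        if list(df.index) != list(df.columns):
            raise ValidationError("distance matrix index and columns differ")
        D = df.to_numpy()
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(D < -1e-12):
            raise ValidationError("negative distances")
        # exact symmetry/zero-diagonal after validation
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        self.data = pd.DataFrame(D, index=df.index, columns=df.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def restrict(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        return DistanceMatrix(self.data.loc[ids, ids], self.metric_tag)


#: canonical column order for DifferentialTable TSV artifacts
DIFFERENTIAL_COLUMNS = [
    "feature",
    "mean_g1",
    "mean_g2",
    "stat",
    "p",
    "q",
    "ratio",
    "vip",
    "pass",
]


@dataclass
class DifferentialTable:
    """Per-feature two-group differential statistics with BH-adjusted q-values.

    ``criteria`` records the thresholds used so that ``pass`` flags can be
    reproduced from the stored columns alone.
    """

    table: pd.DataFrame
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("feature", "p", "q") if c not in self.table.columns]
        if missing:
            raise ValidationError(f"differential table missing column(s): {missing}")
        t = self.table
        if np.any(t["q"].to_numpy() < t["p"].to_numpy() - 1e-12):
            raise ValidationError("q-values below raw p-values")

    @property
    def n_pass(self) -> int:
        return int(self.table["pass"].sum()) if "pass" in self.table.columns else 0

    def passing_features(self) -> list[str]:
        if "pass" not in self.table.columns:
            return []
        return list(self.table.loc[self.table["pass"].astype(bool), "feature"])

    def to_frame(self) -> pd.DataFrame:
        cols = [c for c in DIFFERENTIAL_COLUMNS if c in self.table.columns]
        cols += [c for c in self.table.columns if c not in cols]
        return self.table[cols]


def to_jsonable(obj):
    """Recursively convert results objects / arrays / frames for JSON dumps."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": True,
            "index": list(map(str, obj.index)),
            "columns": list(map(str, obj.columns)),
            "values": obj.to_numpy().tolist(),
        }
    if isinstance(obj, pd.Series):
        return {"__series__": True, "index": list(map(str, obj.index)), "values": obj.to_list()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_jsonable(obj), fh, indent=1, sort_keys=True)
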