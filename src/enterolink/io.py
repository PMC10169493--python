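"""Readers and writers for the pipeline's tabular artifacts.

Canonical on-disk format is TSV with samples as rows and features as columns;
``transpose=True`` accepts the opposite orientation. JSON is used for nested
result objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceTable,
    DifferentialTable,
    DistanceMatrix,
    OmicsMatrix,
    PhenotypeTable,
    ValidationError,
    dump_json,
)

log = logging.getLogger("enterolink")

__all__ = ["read_table", "align_samples", "write_run_artifact", "read_pathway_map"]

_KINDS = ("abundance", "omics", "phenotype", "pathway_map")


def _read_frame(path, transpose: bool) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(f"{path}: non-numeric cell at row {bad[0]!r}, column {col!r}")
        df[col] = coerced
    return df


def read_table(path, kind: str, *, transpose: bool = False, layer_tag: str = "rumen_metab"):
    """Read a TSV/CSV table into the typed container for ``kind``.

    Abundance tables are renormalized to proportions; a deviation of row sums
    from 1 beyond 1e-6 is logged as a warning (rounded published tables are
    common) rather than rejected.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {_KINDS}")
    if kind == "pathway_map":
        return read_pathway_map(path)
    df = _read_frame(path, transpose)
    if kind == "abundance":
        sums = df.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > 1e-6):
            log.warning("%s: row sums deviate from 1 (max |dev| %.3g); renormalizing", path, float(np.max(np.abs(sums - 1.0))))
        return AbundanceTable(df)
    if kind == "omics":
        return OmicsMatrix(df, layer_tag=layer_tag)
    return PhenotypeTable(df)


def read_pathway_map(path) -> pd.DataFrame:
    """Pathway annotation map: columns metabolite_id, pathway_id[, pathway_name]."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    need = {"metabolite_id", "pathway_id"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: pathway map needs columns {sorted(need)}")
    return df


def align_samples(tables: Sequence):
    """Restrict typed tables to their shared samples, in a canonical order.

    Order follows the first table's sample order. Idempotent; dropped ids are
    logged.
    """
    if len(tables) < 2:
        raise ValueError("align_samples needs at least two tables")
    shared = set(tables[0].sample_ids)
    for t in tables[1:]:
        shared &= set(t.sample_ids)
    if not shared:
        raise ValidationError("no shared sample ids across tables")
    order = [s for s in tables[0].sample_ids if s in shared]
    for t in tables:
        dropped = [s for s in t.sample_ids if s not in shared]
        if dropped:
            log.info("align_samples: dropping %d sample(s): %s", len(dropped), dropped)
    return [t.restrict(order) for t in tables]


def write_run_artifact(obj, path, format: str = "tsv") -> Path:
    """Write a result object to disk as TSV (tables) or JSON (nested objects).

    TSV numerics are written at 12 significant digits so that a read/write
    round trip reproduces values at declared precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        dump_json(obj, path)
        return path
    if format != "tsv":
        raise ValueError(f"unknown artifact format {format!r}")
    if isinstance(obj, DifferentialTable):
        frame = obj.to_frame()
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path
    if isinstance(obj, (AbundanceTable, OmicsMatrix, DistanceMatrix, PhenotypeTable)):
        frame = obj.data
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise ValueError(f"cannot serialize {type(obj).__name__} as tsv")
    frame.to_csv(path, sep="\t", float_format="%.12g")
    return path
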