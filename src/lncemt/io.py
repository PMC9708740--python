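"""Readers and writers for the package's interchange formats.

Everything is plain text: expression / clinical / regulon / mutation / RCI
tables as TSV, gene sets as GMT, run configuration as YAML. Write-then-read
round-trips reproduce the in-memory object exactly (ids bit-identical, float
values printed with full ``repr`` precision).
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    RegulonTable,
)

logger = logging.getLogger("lncemt")


def _read_tsv_indexed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _to_numeric_strict(df: pd.DataFrame, path) -> pd.DataFrame:
    def _locate_bad() -> tuple[int, int]:
        for r in range(df.shape[0]):
            for c in range(df.shape[1]):
                v = df.iat[r, c]
                try:
                    if v is None or (isinstance(v, float) and np.isnan(v)):
                        return r, c
                    float(v)
                except (TypeError, ValueError):
                    return r, c
        raise AssertionError("no bad cell found")

    try:
        # astype(float) parses exactly (full double precision round-trip)
        out = df.astype(float)
    except (TypeError, ValueError):
        r, c = _locate_bad()
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        ) from None
    if out.isna().to_numpy().any():
        r, c = _locate_bad()
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_expression(path, biotype_path=None, log2p1: bool = False) -> ExpressionMatrix:
    """Read a features x samples expression TSV plus optional biotype TSV.

    The first column holds feature ids and the header row sample ids. The
    biotype file maps feature id -> {lncRNA, protein_coding, other}; features
    absent from it are labelled ``other``. With ``log2p1`` the values are
    transformed as log2(x + 1) on read (for raw counts/TPM input).
    """
    raw = _read_tsv_indexed(path)
    values = _to_numeric_strict(raw, path)
    if log2p1:
        if (values.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative values are incompatible with --log2p1")
        values = np.log2(values + 1.0)
    if biotype_path is not None:
        bt_df = pd.read_csv(
            biotype_path, sep="\t", index_col=0, dtype=str, header=None
        ).squeeze("columns")
        if isinstance(bt_df, pd.DataFrame):  # header present
            bt_df = pd.read_csv(biotype_path, sep="\t", index_col=0, dtype=str).iloc[:, 0]
        biotype = pd.Series(bt_df)
    else:
        biotype = pd.Series("other", index=values.index, dtype=object)
    return ExpressionMatrix(values, biotype)


def write_expression(expr: ExpressionMatrix, path, biotype_path=None) -> None:
    df = expr.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=None)
    if biotype_path is not None:
        expr.biotype.rename("biotype").to_csv(
            biotype_path, sep="\t", header=False
        )


def read_biotypes(path) -> pd.Series:
    s = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=None).iloc[:, 0]
    s.index = s.index.astype(str)
    return s


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name <TAB> description <TAB> gene1 <TAB> ...``.

    The description column is discarded; duplicate genes within a set are
    dropped (order preserved) with a logged warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "gene set %r: %d duplicate gene(s) removed",
                    name,
                    len(genes) - len(deduped),
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = deduped
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            fh.write("\t".join([name, description, *collection[name]]) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV: sample_id, os_time, os_event[, stage, ...]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path) -> None:
    df = clin.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_regulons(path) -> RegulonTable:
    """Read a signed regulon TSV with columns tf, target, mode (+1/-1)."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    return RegulonTable(df)


def write_regulons(reg: RegulonTable, path) -> None:
    reg.table.to_csv(path, sep="\t", index=False)


def read_matrix_generic(path) -> pd.DataFrame:
    """Read any numeric id-indexed matrix TSV (mutations, scores, ...)."""
    raw = _read_tsv_indexed(path)
    return _to_numeric_strict(raw, path)


def write_matrix_generic(df: pd.DataFrame, path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_rci(path) -> pd.Series:
    """Read a 2-column lncRNA -> RCI table (relative concentration index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    if not np.isfinite(s.to_numpy()).all():
        bad = s.index[~np.isfinite(s.to_numpy())][0]
        raise ValueError(f"{path}: non-finite RCI value for {bad!r}")
    return s.rename("rci")


def write_manifest(path, config, stages: Iterable[str]) -> None:
    """Write a YAML run manifest (seed, config, executed stages)."""
    import dataclasses

    import yaml

    payload = {
        "config": dataclasses.asdict(config),
        "stages": list(stages),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return path
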