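"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (first column = row id, header = sample ids),
gene sets as standard GMT lines (name, description, tab-separated
genes), clinical tables as TSV with "NA" for missing values.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection
from .synthetic import SyntheticCohort

logger = logging.getLogger("tmescore")

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "write_cohort",
]


class ExpressionFormatError(ValueError):
    """Malformed expression TSV."""


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes x samples TSV; collapse duplicate gene ids.

    Duplicate gene ids keep the row with the higher mean expression.
    Non-numeric cells raise with 1-based data coordinates.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ExpressionFormatError(f"{path}: empty file")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.shape[1] == 0:
        raise ExpressionFormatError(f"{path}: no sample columns in header")
    try:
        mat = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            conv = pd.to_numeric(raw[col], errors="coerce")
            bad = conv.isna() & raw[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ExpressionFormatError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1} "
                    f"(gene {raw.index[i]!r}, sample {col!r}): {raw[col].iloc[i]!r}"
                ) from None
        raise
    if mat.isna().any().any():
        i, j = np.argwhere(mat.isna().to_numpy())[0]
        raise ExpressionFormatError(
            f"{path}: missing value at row {i + 1}, column {j + 1}"
        )
    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].unique()
        logger.warning("collapsing %d duplicate gene id(s) by higher row mean", len(dupes))
        mat = (
            mat.assign(_mean=mat.mean(axis=1))
            .sort_values("_mean", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
            .loc[mat.index.drop_duplicates()]
        )
    return mat


def write_expression(expr: pd.DataFrame, path: str | os.PathLike, gene_col: str = "gene") -> None:
    expr.rename_axis(gene_col).to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: one set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(sets, source=str(path))


def write_gmt(sets: GeneSetCollection, path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Clinical TSV indexed by the first column; "NA" means missing."""
    clin = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    for col in ("os_time", "os_event"):
        if col not in clin.columns:
            raise ValueError(f"{path}: clinical table must have a {col!r} column")
    clin["os_time"] = clin["os_time"].astype(float)
    clin["os_event"] = clin["os_event"].astype(int)
    if (clin["os_time"] <= 0).any():
        raise ValueError(f"{path}: os_time must be positive")
    if not clin["os_event"].isin([0, 1]).all():
        raise ValueError(f"{path}: os_event must be 0/1")
    return clin


def write_clinical(clin: pd.DataFrame, path: str | os.PathLike) -> None:
    clin.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write expression TSV, clinical TSV (with truth), and signature GMT."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "signatures": outdir / "signatures.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(cohort.signatures, paths["signatures"])
    cohort.truth.rename_axis("sample_id").to_frame().to_csv(paths["truth"], sep="\t")
    return paths
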