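"""Readers and writers for all pipeline tables, plus configuration loading.

All tables are tab-separated text.  Output files start with ``#``-prefixed
header comments recording the parameters and seed that produced them;
readers skip such comments.  Missing values are empty cells.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    Karyotype,
    Parameters,
    ValidationError,
    validate_annotation,
)

log = logging.getLogger("dosagecomp")

SILAC_COLUMNS = ("strain_id", "protein_id", "time_min", "hl_ratio")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_expression_matrix(path, layer: str) -> ExpressionMatrix:
    """Read a gene x strain abundance TSV (first column gene_id).

    Empty cells become missing.  On the mRNA layer, zeros are converted to
    missing as well (only non-zero counts-per-million are meaningful);
    zeros on other layers are rejected.  Duplicate gene rows and
    non-numeric cells are errors.
    """
    raw = _read_tsv(path)
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    raw.index.name = "gene_id"
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique()
        raise ValidationError(
            f"{path}: duplicate gene rows: {list(dupes)[:5]}"
        )
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        values[col] = converted
    if layer == "mRNA":
        n_zero = int((values == 0).sum().sum())
        if n_zero:
            log.info("mRNA layer: converting %d zero entries to missing", n_zero)
        values = values.mask(values == 0)
    return ExpressionMatrix(layer=layer, values=values)


def write_expression_matrix(matrix: ExpressionMatrix, path, comments=()) -> None:
    write_table(matrix.values, path, comments=comments, index_label="gene_id")


def write_table(df: pd.DataFrame, path, comments=(), params: Parameters | None = None,
                seed: int | None = None, index_label=None, index=True) -> None:
    """Write a TSV with ``#`` header comments recording provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        if params is not None:
            for key, val in params.as_dict().items():
                fh.write(f"# param {key}: {val}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, na_rep="")


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_karyotypes(path) -> list[Karyotype]:
    """Read a strain table: ``strain_id``, ``ploidy``, one column per chromosome."""
    df = _read_tsv(path)
    needed = {"strain_id", "ploidy"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: karyotype table needs columns {sorted(needed)}")
    chrom_cols = [c for c in df.columns if c not in needed]
    if not chrom_cols:
        raise ValidationError(f"{path}: no chromosome columns found")
    if df["strain_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate strain_id rows")
    karyotypes = []
    for _, row in df.iterrows():
        try:
            cn = {c: float(row[c]) for c in chrom_cols}
            ploidy = float(row["ploidy"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-numeric entry for strain {row['strain_id']!r}"
            ) from exc
        if ploidy != int(ploidy):
            raise ValidationError(
                f"{path}: ploidy must be an integer for strain {row['strain_id']!r}"
            )
        karyotypes.append(
            Karyotype(strain_id=str(row["strain_id"]), ploidy=int(ploidy),
                      chrom_cn=cn)
        )
    return karyotypes


def write_karyotypes(karyotypes: list[Karyotype], path, comments=()) -> None:
    chroms = sorted({c for k in karyotypes for c in k.chrom_cn})
    rows = []
    for k in karyotypes:
        row = {"strain_id": k.strain_id, "ploidy": k.ploidy}
        row.update({c: k.chrom_cn.get(c, k.ploidy) for c in chroms})
        rows.append(row)
    write_table(pd.DataFrame(rows), path, comments=comments, index=False)


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV; ``gene_sets`` is a semicolon-joined field."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: annotation needs a gene_id column")
    df = df.set_index("gene_id")
    if "gene_sets" in df.columns:
        df["gene_sets"] = [
            frozenset(str(s).split(";")) if isinstance(s, str) and s else frozenset()
            for s in df["gene_sets"]
        ]
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path, comments=()) -> None:
    out = annotation.copy()
    if "gene_sets" in out.columns:
        out["gene_sets"] = [";".join(sorted(s)) for s in out["gene_sets"]]
    write_table(out, path, comments=comments, index_label="gene_id")


def read_silac_table(path) -> pd.DataFrame:
    """Read a long-format SILAC table: strain_id, protein_id, time_min, hl_ratio.

    Ratios and times must be positive; series of any length are retained
    (the minimum-two-time-points rule is applied by the turnover fits).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SILAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: SILAC table lacks columns {sorted(missing)}")
    df = df.loc[:, list(SILAC_COLUMNS)].copy()
    df["time_min"] = pd.to_numeric(df["time_min"])
    df["hl_ratio"] = pd.to_numeric(df["hl_ratio"])
    if (df["hl_ratio"] <= 0).any():
        bad = df.loc[df["hl_ratio"] <= 0].iloc[0]
        raise ValidationError(
            f"{path}: non-positive H/L ratio {bad['hl_ratio']} for "
            f"({bad['strain_id']}, {bad['protein_id']}, t={bad['time_min']})"
        )
    if (df["time_min"] <= 0).any():
        raise ValidationError(f"{path}: time points must be positive")
    n_short = int(
        (df.groupby(["strain_id", "protein_id"])["time_min"].size() < 2).sum()
    )
    if n_short:
        log.info("SILAC table: %d series have a single time point", n_short)
    return df


def load_config(path=None, overrides: dict | None = None) -> Parameters:
    """Load analysis parameters from a YAML file; absent keys take defaults.

    Unknown keys raise an error listing the valid ones.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        data = loaded or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: configuration must be a mapping")
    if overrides:
        data.update(overrides)
    valid = set(Parameters.field_names())
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(
            f"unknown configuration keys {sorted(unknown)}; "
            f"valid keys: {sorted(valid)}"
        )
    params = Parameters(**data)
    log.info("parameters: %s", params.as_dict())
    return params
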