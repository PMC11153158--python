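"""Dynamic-SILAC turnover estimation and turnover–attenuation analyses.

After a pulse to heavy lysine, the heavy/light peptide ratio of a protein
grows with its degradation/dilution rate kdp.  Rates are estimated per
(strain, protein) by least squares on the log-transformed H/L time course
(natural log; the only place the package leaves base 2):

* ``literal`` (default): OLS of ln(H/L) on time, with intercept — the
  direct reading of fitting "time points against the log-transformed H/L
  ratios";
* ``kinetic``: OLS of ln(1 + H/L) on time through the origin — the exact
  solution of first-order label incorporation, H/L = exp(kdp t) - 1.

Half-life is ln(2)/kdp.  No doubling-time or dilution correction is
applied by default (most yeast proteins are stable on the 3-h window);
``doubling_time_min`` subtracts the growth-dilution rate if provided.

The turnover matrix is filtered to proteins measured in >= 80% of
strains, KNN-imputed, quantile-normalized across strains, and compared
across expression contexts (aneuploid chromosome / euploid chromosome of
aneuploid strain / euploid chromosome of euploid strain).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import Karyotype, RelativeMatrix, ValidationError, gene_chromosomes
from .preprocess import knn_impute
from .stats import ols_line, ols_through_origin, quantile_normalize

log = logging.getLogger("dosagecomp")

__all__ = [
    "fit_turnover",
    "turnover_matrix",
    "filter_impute_turnover",
    "quantile_normalize",
    "context_turnover",
    "attenuation_turnover_correlation",
    "expression_turnover_correlation",
    "deletion_collection_contrast",
]

CONTEXT_ANEUPLOID = "aneuploid_chromosome"
CONTEXT_EU_OF_ANEU = "euploid_chromosome_of_aneuploid_strain"
CONTEXT_EU_OF_EU = "euploid_chromosome_of_euploid_strain"


def fit_turnover(silac: pd.DataFrame, transform: str = "literal",
                 doubling_time_min: float | None = None) -> pd.DataFrame:
    """Per-(strain, protein) turnover rate from a long-format SILAC table.

    Series need >= 2 time points with positive ratios.  Non-positive
    fitted slopes are retained with ``valid = False`` and excluded from
    half-life computation.
    """
    if transform not in ("literal", "kinetic"):
        raise ValidationError(f"unknown transform {transform!r}")
    rows = []
    for (strain, protein), grp in silac.groupby(["strain_id", "protein_id"]):
        t = grp["time_min"].to_numpy(dtype=float)
        r = grp["hl_ratio"].to_numpy(dtype=float)
        ok = (r > 0) & (t > 0)
        t, r = t[ok], r[ok]
        if t.size < 2:
            continue
        if transform == "literal":
            y = np.log(r)
            if np.unique(t).size < 2:
                continue
            k, _, r2 = ols_line(t, y)
        else:
            y = np.log1p(r)
            k = ols_through_origin(t, y)
            ss_res = float(np.sum((y - k * t) ** 2))
            ss_tot = float(np.sum(y ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot else np.nan
        if doubling_time_min:
            k -= math.log(2) / doubling_time_min
        valid = k > 0
        rows.append(
            {
                "strain_id": strain,
                "protein_id": protein,
                "kdp": float(k),
                "half_life": math.log(2) / k if valid else np.nan,
                "n_timepoints": int(t.size),
                "fit_r2": float(r2),
                "valid": bool(valid),
            }
        )
    out = pd.DataFrame(
        rows, columns=["strain_id", "protein_id", "kdp", "half_life",
                       "n_timepoints", "fit_r2", "valid"],
    )
    n_invalid = int((~out["valid"]).sum()) if len(out) else 0
    if n_invalid:
        log.info("turnover fits: %d series with non-positive kdp flagged invalid",
                 n_invalid)
    return out


def turnover_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Protein x strain kdp grid from valid turnover records."""
    valid = records[records["valid"]]
    return valid.pivot_table(
        index="protein_id", columns="strain_id", values="kdp", aggfunc="first"
    )


def filter_impute_turnover(matrix: pd.DataFrame,
                           presence_fraction: float = 0.8,
                           k: int = 10) -> pd.DataFrame:
    """Keep proteins with rates in >= ``presence_fraction`` of strains and
    KNN-impute the remaining gaps (e.g. 44/55 strains at the 80% default)."""
    n_strains = matrix.shape[1]
    if n_strains < 5:
        raise ValidationError("turnover filtering needs >= 5 strains")
    cutoff = math.ceil(presence_fraction * n_strains - 1e-9)
    keep = matrix.notna().sum(axis=1) >= cutoff
    if not keep.any():
        raise ValidationError("no protein passes the turnover presence filter")
    filtered = matrix.loc[keep]
    log.info("turnover filter: %d/%d proteins present in >= %d/%d strains",
             int(keep.sum()), len(keep), cutoff, n_strains)
    if filtered.isna().any().any():
        filtered = knn_impute(filtered, k=k, log_scale=True)
    return filtered


def _strain_context(kary: Karyotype, chrom: str) -> str:
    if chrom in kary.aneuploid_chromosomes:
        return CONTEXT_ANEUPLOID
    return CONTEXT_EU_OF_EU if kary.is_euploid else CONTEXT_EU_OF_ANEU


def context_turnover(qnorm: pd.DataFrame, karyotypes: list[Karyotype],
                     annotation: pd.DataFrame,
                     min_occurrences: int = 3) -> tuple[pd.DataFrame, dict]:
    """Median quantile-normalized rate per protein per expression context.

    Only proteins with >= ``min_occurrences`` rates in the aneuploid
    context and in each euploid context are compared.  The summary counts
    proteins whose aneuploid-context median exceeds each euploid-context
    median.
    """
    by_id = {k.strain_id: k for k in karyotypes}
    chroms = gene_chromosomes(annotation, qnorm.index)
    rows = []
    for protein in qnorm.index:
        chrom = chroms[protein]
        buckets: dict[str, list[float]] = {
            CONTEXT_ANEUPLOID: [], CONTEXT_EU_OF_ANEU: [], CONTEXT_EU_OF_EU: []
        }
        for strain in qnorm.columns:
            val = qnorm.at[protein, strain]
            if not np.isfinite(val) or strain not in by_id:
                continue
            buckets[_strain_context(by_id[strain], chrom)].append(float(val))
        if (
            len(buckets[CONTEXT_ANEUPLOID]) < min_occurrences
            or len(buckets[CONTEXT_EU_OF_ANEU]) < min_occurrences
            or len(buckets[CONTEXT_EU_OF_EU]) < min_occurrences
        ):
            continue
        rows.append(
            {
                "protein_id": protein,
                "median_aneuploid": float(np.median(buckets[CONTEXT_ANEUPLOID])),
                "median_euploid_of_aneuploid": float(
                    np.median(buckets[CONTEXT_EU_OF_ANEU])
                ),
                "median_euploid_of_euploid": float(
                    np.median(buckets[CONTEXT_EU_OF_EU])
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame(
        columns=["median_aneuploid", "median_euploid_of_aneuploid",
                 "median_euploid_of_euploid"]
    )
    summary = {
        "n_proteins": int(len(table)),
        "aneuploid_higher_than_euploid_of_euploid": int(
            (table["median_aneuploid"] > table["median_euploid_of_euploid"]).sum()
        ) if len(table) else 0,
        "aneuploid_higher_than_euploid_of_aneuploid": int(
            (table["median_aneuploid"] > table["median_euploid_of_aneuploid"]).sum()
        ) if len(table) else 0,
    }
    return table, summary


def attenuation_turnover_correlation(median_turnover: pd.Series,
                                     attenuation_pct: pd.Series) -> dict:
    """Pearson correlation (and OLS line) between per-strain median turnover
    and protein-level attenuation percentage across aneuploid isolates."""
    paired = pd.DataFrame(
        {"turnover": median_turnover, "attenuation": attenuation_pct}
    ).dropna()
    if len(paired) < 3:
        raise ValidationError("attenuation-turnover correlation needs >= 3 strains")
    if paired["turnover"].std(ddof=1) == 0 or paired["attenuation"].std(ddof=1) == 0:
        raise ValidationError("zero-variance input")
    res = sps.pearsonr(paired["turnover"], paired["attenuation"])
    slope, intercept, r2 = ols_line(paired["turnover"], paired["attenuation"])
    return {
        "r": float(res.statistic), "p_value": float(res.pvalue),
        "slope": slope, "intercept": intercept, "n_strains": int(len(paired)),
    }


def expression_turnover_correlation(rel: RelativeMatrix,
                                    strain_turnover: pd.Series,
                                    karyotypes: list[Karyotype],
                                    annotation: pd.DataFrame,
                                    min_occurrences: int = 3) -> pd.DataFrame:
    """Per-protein Pearson r between expression ratio and isolate turnover.

    One r per protein per expression context (aneuploid chromosome,
    euploid chromosome of euploid isolate, euploid chromosome of aneuploid
    isolate), computed over the >= ``min_occurrences`` qualifying strains;
    the output carries complex membership for stratified summaries.
    """
    by_id = {k.strain_id: k for k in karyotypes}
    chroms = gene_chromosomes(annotation, rel.values.index)
    complex_member = annotation.loc[rel.values.index, "complex_member"]
    strains = [s for s in rel.values.columns
               if s in strain_turnover.index and s in by_id]
    rows = []
    for protein in rel.values.index:
        chrom = chroms[protein]
        buckets: dict[str, list[tuple[float, float]]] = {}
        for strain in strains:
            expr = rel.values.at[protein, strain]
            turn = strain_turnover[strain]
            if not (np.isfinite(expr) and np.isfinite(turn)):
                continue
            ctx = _strain_context(by_id[strain], chrom)
            buckets.setdefault(ctx, []).append((float(expr), float(turn)))
        for ctx, pairs in buckets.items():
            if len(pairs) < min_occurrences:
                continue
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(sps.pearsonr(x, y).statistic)
            rows.append(
                {
                    "protein_id": protein,
                    "context": ctx,
                    "r": r,
                    "n_strains": len(pairs),
                    "complex_member": bool(complex_member[protein]),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "context", "r", "n_strains", "complex_member"]
    )


def deletion_collection_contrast(abundance: pd.DataFrame,
                                 annotation: pd.DataFrame,
                                 reference_half_lives: pd.Series,
                                 duplication_log2_threshold: float = 0.8) -> dict:
    """Half-life dependence of dosage response in a deletion-style collection.

    Fold changes are ratios of each protein's abundance to its cross-strain
    median.  A chromosome is called duplicated in a strain when the median
    log2 fold change over its measured proteins exceeds the threshold; the
    log2 fold changes of duplicated-chromosome proteins are averaged across
    such strains, and a Welch two-sided t-test contrasts proteins in the
    short (< Q1) versus long (> Q3) reference-half-life groups.
    """
    chroms = gene_chromosomes(annotation, abundance.index)
    ref_median = abundance.median(axis=1, skipna=True)
    log2_fc = np.log2(abundance.div(ref_median, axis=0))

    calls = []
    per_protein_chunks: dict[str, list[float]] = {}
    for strain in log2_fc.columns:
        col = log2_fc[strain]
        chrom_medians = col.groupby(chroms.to_numpy()).median()
        for chrom, med in chrom_medians.items():
            if np.isfinite(med) and med > duplication_log2_threshold:
                calls.append({"strain_id": strain, "chromosome": chrom,
                              "median_log2_fc": float(med)})
                on_chrom = col[(chroms == chrom).to_numpy()].dropna()
                for protein, fc in on_chrom.items():
                    per_protein_chunks.setdefault(protein, []).append(float(fc))
    calls_df = pd.DataFrame(calls, columns=["strain_id", "chromosome",
                                            "median_log2_fc"])
    if calls_df.empty:
        log.warning("deletion-collection contrast: no duplicated chromosome detected")
        return {"calls": calls_df, "t_stat": np.nan, "p_value": np.nan,
                "mean_short": np.nan, "mean_long": np.nan, "n_short": 0,
                "n_long": 0}

    mean_fc = pd.Series(
        {p: float(np.mean(v)) for p, v in per_protein_chunks.items()}
    )
    hl = reference_half_lives.reindex(mean_fc.index).dropna()
    q1, q3 = hl.quantile([0.25, 0.75])
    short = mean_fc[hl.index[hl < q1]]
    long_ = mean_fc[hl.index[hl > q3]]
    if len(short) < 2 or len(long_) < 2:
        raise ValidationError("need >= 2 proteins in each half-life group")
    res = sps.ttest_ind(short, long_, equal_var=False)
    return {
        "calls": calls_df,
        "t_stat": float(res.statistic),
        "p_value": float(res.pvalue),
        "mean_short": float(short.mean()),
        "mean_long": float(long_.mean()),
        "n_short": int(len(short)),
        "n_long": int(len(long_)),
    }
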