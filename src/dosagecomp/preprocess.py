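"""Precursor-level QC, batch correction, protein summarization, imputation.

Mirrors the post-search filters applied to the cohort proteomes: sample
outlier exclusion (|z| > 2.5 on total signal or precursor count), the
80%-presence / QC-CV < 0.3 precursor filter, per-batch median centering
(one multiplicative factor per batch), protein summarization and KNN
imputation of residual missing values.

CVs are computed on linear-scale intensities, the field's convention.
Protein summarization uses the median of present precursors; an external
quantifier can be plugged in via ``summarize_proteins(..., summarizer=)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .datatypes import ExpressionMatrix, ValidationError

log = logging.getLogger("dosagecomp")


@dataclass
class QCReport:
    """Bookkeeping for the precursor-level QC funnel."""

    n_precursors_in: int = 0
    n_precursors_out: int = 0
    dropped_by_presence: int = 0
    dropped_by_cv: int = 0
    outlier_samples: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_medians_before: dict[str, float] = field(default_factory=dict)
    batch_medians_after: dict[str, float] = field(default_factory=dict)

    def check_consistent(self) -> None:
        dropped = self.n_precursors_in - self.n_precursors_out
        # a precursor can fail both filters; the individual counts may overlap
        if dropped < 0 or dropped > self.dropped_by_presence + self.dropped_by_cv:
            raise ValidationError("QC report counts are inconsistent")


def detect_outlier_samples(matrix: ExpressionMatrix | pd.DataFrame,
                           outlier_z: float = 2.5,
                           report: QCReport | None = None) -> list[str]:
    """Flag samples whose total signal or precursor count is a z-outlier.

    z-scores are computed against the cohort mean and sample standard
    deviation (ddof=1); a sample is excluded if |z| > ``outlier_z`` on
    either the column sum of present intensities (the TIC analogue) or the
    number of present precursors.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 3:
        raise ValidationError("outlier detection needs at least 3 samples")
    totals = values.sum(axis=0, skipna=True)
    counts = values.notna().sum(axis=0).astype(float)
    flagged: list[str] = []
    details = {}
    for name, series in (("total_signal", totals), ("precursor_count", counts)):
        sd = series.std(ddof=1)
        if sd == 0:
            continue
        z = (series - series.mean()) / sd
        for sample in z.index[z.abs() > outlier_z]:
            details.setdefault(sample, {})[f"z_{name}"] = float(z[sample])
            if sample not in flagged:
                flagged.append(sample)
    if report is not None:
        report.outlier_samples.update(details)
    if flagged:
        log.info("excluding %d outlier samples: %s", len(flagged), flagged)
    return flagged


def filter_precursors(matrix: ExpressionMatrix, qc_sample_ids: list[str],
                      presence_fraction: float = 0.8,
                      qc_cv_max: float = 0.3,
                      report: QCReport | None = None) -> ExpressionMatrix:
    """Keep precursors present in >= ``presence_fraction`` of strain samples
    and with linear-scale CV < ``qc_cv_max`` across the QC samples.

    Precursors with fewer than two present QC values cannot demonstrate
    their precision and are dropped with the CV failures.
    """
    qc_ids = list(qc_sample_ids)
    if not qc_ids:
        raise ValidationError("filter_precursors requires QC samples")
    missing = set(qc_ids) - set(matrix.values.columns)
    if missing:
        raise ValidationError(f"QC samples absent from matrix: {sorted(missing)}")
    strain_cols = [c for c in matrix.values.columns if c not in qc_ids]
    strains = matrix.values[strain_cols]
    qc = matrix.values[qc_ids]

    presence = strains.notna().mean(axis=1)
    pass_presence = presence >= presence_fraction

    qc_mean = qc.mean(axis=1, skipna=True)
    qc_sd = qc.std(axis=1, ddof=1, skipna=True)
    cv = qc_sd / qc_mean
    pass_cv = (qc.notna().sum(axis=1) >= 2) & (cv < qc_cv_max)

    keep = pass_presence & pass_cv
    if report is not None:
        report.n_precursors_in = int(matrix.values.shape[0])
        report.dropped_by_presence = int((~pass_presence).sum())
        report.dropped_by_cv = int((~pass_cv).sum())
        report.n_precursors_out = int(keep.sum())
        report.check_consistent()
    log.info(
        "precursor filter: %d/%d retained (%d fail presence, %d fail QC CV)",
        int(keep.sum()), len(keep), int((~pass_presence).sum()),
        int((~pass_cv).sum()),
    )
    meta = matrix.strain_meta
    return ExpressionMatrix(matrix.layer, matrix.values.loc[keep], meta)


def batch_median_center(matrix: ExpressionMatrix | pd.DataFrame,
                        batches: pd.Series,
                        report: QCReport | None = None) -> ExpressionMatrix | pd.DataFrame:
    """Bring each batch's median precursor intensity to the global median.

    The correction is a single multiplicative factor per batch (additive
    in log2), so within-batch rank order is untouched.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    unlabeled = values.columns.difference(batches.index)
    if len(unlabeled):
        raise ValidationError(f"samples without batch label: {list(unlabeled)[:5]}")
    global_median = float(np.nanmedian(values.to_numpy(dtype=float)))
    corrected = values.copy()
    for batch, cols in values.columns.groupby(batches[values.columns]).items():
        block = values[cols].to_numpy(dtype=float)
        if np.all(np.isnan(block)):
            raise ValidationError(f"batch {batch!r} has no present values")
        batch_median = float(np.nanmedian(block))
        factor = global_median / batch_median
        corrected[cols] = values[cols] * factor
        if report is not None:
            report.batch_medians_before[batch] = batch_median
            report.batch_medians_after[batch] = float(
                np.nanmedian(corrected[cols].to_numpy(dtype=float))
            )
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(matrix.layer, corrected, matrix.strain_meta)
    return corrected


def summarize_proteins(matrix: ExpressionMatrix, precursor_map: pd.Series,
                       summarizer=None) -> ExpressionMatrix:
    """Collapse precursors to proteins (default: median of present precursors).

    ``precursor_map`` maps precursor_id -> protein_id and must cover every
    precursor row.  ``summarizer`` may be any callable mapping a
    precursor-block DataFrame to a per-sample Series, allowing an external
    quantifier to be plugged in.
    """
    unmapped = matrix.values.index.difference(precursor_map.index)
    if len(unmapped):
        raise ValidationError(f"unmapped precursors: {list(unmapped)[:5]}")
    summarizer = summarizer or (lambda block: block.median(axis=0, skipna=True))
    grouped = matrix.values.groupby(precursor_map[matrix.values.index].to_numpy())
    protein_values = grouped.apply(summarizer)
    protein_values.index.name = "gene_id"
    meta = matrix.strain_meta
    return ExpressionMatrix("protein", protein_values, meta)


def knn_impute(values: pd.DataFrame, k: int = 10,
               log_scale: bool = True) -> pd.DataFrame:
    """Impute missing cells from the k nearest rows.

    Distances are Euclidean over mutually present columns on the log2
    scale, rescaled by the shared-column count (sklearn's NaN-aware
    Euclidean); a missing cell takes the average of the same column's
    values in the ``k`` nearest rows that have it, falling back to the row
    mean when no neighbouring row does.  Present values are never altered.
    """
    if values.isna().all(axis=1).any():
        bad = values.index[values.isna().all(axis=1)]
        raise ValidationError(f"rows with no present values: {list(bad)[:5]}")
    frac_missing = float(values.isna().to_numpy().mean())
    if frac_missing >= 0.5:
        raise ValidationError(
            f"overall missingness {frac_missing:.0%} too high for KNN imputation"
        )
    work = np.log2(values.to_numpy(dtype=float)) if log_scale else (
        values.to_numpy(dtype=float).copy()
    )
    dist = nan_euclidean_distances(work, work)
    np.fill_diagonal(dist, np.inf)
    out = work.copy()
    missing_rows, missing_cols = np.where(np.isnan(work))
    row_means = np.nanmean(work, axis=1)
    for i, j in zip(missing_rows, missing_cols):
        candidates = np.where(~np.isnan(work[:, j]) & np.isfinite(dist[i]))[0]
        if candidates.size == 0:
            out[i, j] = row_means[i]
            continue
        nearest = candidates[np.argsort(dist[i, candidates], kind="stable")[:k]]
        out[i, j] = work[nearest, j].mean()
    if log_scale:
        out = 2.0 ** out
        out[~np.isnan(values.to_numpy(dtype=float))] = values.to_numpy(dtype=float)[
            ~np.isnan(values.to_numpy(dtype=float))
        ]
    return pd.DataFrame(out, index=values.index, columns=values.columns)
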