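"""Strain-by-strain and chromosome-wide dosage-compensation statistics.

For every (strain, relative-CN-change class) the normalized log2 ratios of
the genes on the affected chromosomes are compared to the expected median
(the CN change itself) with a two-sided one-sample Wilcoxon signed-rank
test; the Hodges–Lehmann pseudomedian of the ratios yields the strain's
attenuation percentage, 100 (1 - pseudomedian / CN change).  Strains whose
protein-level pseudomedian sits inside the open (-0.1, 0.1) band are
marked as reverted to euploidy.  Pooled per-class distribution summaries,
the dosage-response line over class medians, and the aneuploid protein
load complete the strain-level picture.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    Karyotype,
    RelativeMatrix,
    ValidationError,
    gene_chromosomes,
)
from .stats import bh_adjust, ols_line, pseudomedian, wilcoxon_onesample

log = logging.getLogger("dosagecomp")

MIN_GENES_PER_TEST = 5


def _cn_classes(karyotype: Karyotype) -> dict[float, list[str]]:
    """Aneuploid chromosomes grouped by their relative CN change."""
    classes: dict[float, list[str]] = {}
    for chrom, delta in karyotype.relative_cn().items():
        if delta != 0:
            classes.setdefault(round(delta, 9), []).append(chrom)
    return classes


def strain_wilcoxon(rel: RelativeMatrix, karyotypes: list[Karyotype],
                    annotation: pd.DataFrame,
                    min_genes: int = MIN_GENES_PER_TEST) -> pd.DataFrame:
    """One test per (strain, CN-change class); BH across the whole layer.

    The pseudomedian is the median of all Walsh averages of the class's
    log2 ratios; the signed-rank test compares those ratios (shifted by
    the class value) to 0, exactly for n <= 25 without ties and with the
    continuity-corrected normal approximation otherwise.  ``attenuation_pct``
    is reported only for strains whose aneuploid chromosomes share a
    single CN-change class.
    """
    chroms = gene_chromosomes(annotation, rel.values.index)
    rows = []
    for kary in karyotypes:
        if kary.strain_id not in rel.values.columns:
            continue
        classes = _cn_classes(kary)
        single_class = len(classes) == 1
        col = rel.values[kary.strain_id]
        for cn_class, class_chroms in sorted(classes.items()):
            ratios = col[chroms.isin(class_chroms).to_numpy()].dropna().to_numpy()
            if ratios.size < min_genes:
                log.warning(
                    "strain %s class %.3f: only %d genes, test skipped",
                    kary.strain_id, cn_class, ratios.size,
                )
                continue
            stat, p, method = wilcoxon_onesample(ratios, mu=cn_class)
            pm = pseudomedian(ratios)
            rows.append(
                {
                    "strain_id": kary.strain_id,
                    "layer": rel.layer,
                    "cn_class": float(cn_class),
                    "n_genes": int(ratios.size),
                    "pseudomedian": pm,
                    "p_raw": p,
                    "test_method": method,
                    "attenuation_pct": (
                        100.0 * (1.0 - pm / cn_class) if single_class else np.nan
                    ),
                }
            )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_adj"] = bh_adjust(tests["p_raw"])
        tests["p_adj"] = np.maximum(tests["p_adj"], tests["p_raw"])
    else:
        tests = pd.DataFrame(
            columns=["strain_id", "layer", "cn_class", "n_genes", "pseudomedian",
                     "p_raw", "test_method", "attenuation_pct", "p_adj"]
        )
    return tests


def detect_reverted(protein_tests: pd.DataFrame, karyotypes: list[Karyotype],
                    band: tuple[float, float] = (-0.1, 0.1)) -> list[str]:
    """Mark strains as reverted to euploidy from protein pseudomedians.

    A strain is reverted iff it has at least one protein-layer class test
    and every class pseudomedian lies strictly inside the open band
    (exact endpoints count as not reverted).  The flag is set on the
    karyotypes in place and the reverted strain ids returned.
    """
    lo, hi = band
    reverted = []
    by_strain = protein_tests.groupby("strain_id")["pseudomedian"]
    flags = {
        strain: bool(((pms > lo) & (pms < hi)).all())
        for strain, pms in by_strain
    }
    for kary in karyotypes:
        if kary.is_euploid:
            kary.reverted = False
            continue
        kary.reverted = flags.get(kary.strain_id, False)
        if kary.reverted:
            reverted.append(kary.strain_id)
    if reverted:
        log.info("reverted-to-euploid strains: %s", reverted)
    return reverted


def summarize_distributions(rel: RelativeMatrix, cn_table: pd.DataFrame,
                            annotation: pd.DataFrame,
                            gains_min_genes: int = 300,
                            losses_min_genes: int = 50) -> pd.DataFrame:
    """Pooled per-CN-class distribution summaries across all strains.

    Gains with fewer than ``gains_min_genes`` pooled data points (and
    losses with fewer than ``losses_min_genes``) are flagged as excluded
    from visualization; the values are still reported.
    """
    chroms = gene_chromosomes(annotation, rel.values.index)
    pooled: dict[float, list[np.ndarray]] = {}
    for strain in rel.values.columns:
        if strain not in cn_table.index:
            continue
        deltas = cn_table.loc[strain]
        col = rel.values[strain]
        for cn_class in deltas.unique():
            class_chroms = deltas.index[deltas == cn_class]
            vals = col[chroms.isin(class_chroms).to_numpy()].dropna().to_numpy()
            if vals.size:
                pooled.setdefault(round(float(cn_class), 9), []).append(vals)
    rows = []
    for cn_class, chunks in sorted(pooled.items()):
        vals = np.concatenate(chunks)
        cutoff = gains_min_genes if cn_class > 0 else losses_min_genes
        rows.append(
            {
                "cn_class": cn_class,
                "n_points": int(vals.size),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
                "excluded_from_visualization": (
                    cn_class != 0 and vals.size < cutoff
                ),
            }
        )
    return pd.DataFrame(rows)


def fit_dosage_response(summary: pd.DataFrame) -> dict:
    """OLS of per-class median expression on the CN change, gains only.

    Slope 1 means expression follows dosage; slope 1 - a corresponds to an
    average attenuation of 100 a percent across CN-change classes.
    """
    gains = summary[summary["cn_class"] > 0]
    if len(gains) < 2:
        raise ValidationError("dosage-response fit needs >= 2 gain classes")
    slope, intercept, r2 = ols_line(gains["cn_class"], gains["median"])
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "n_classes": int(len(gains)),
        "average_attenuation_pct": 100.0 * (1.0 - slope),
    }


def aneuploid_protein_load(karyotype: Karyotype, annotation: pd.DataFrame,
                           method: str = "surplus",
                           min_coverage: float = 0.5) -> tuple[float, int]:
    """Ploidy-adjusted absolute protein copies encoded on aneuploid chromosomes.

    ``surplus`` (default) weights each gene's copies/cell by
    |CN/ploidy - 1| (the surplus or deficit relative to euploid);
    ``dosage`` weights by CN/ploidy and is offered without endorsement.
    Genes lacking ``copies_per_cell`` are ignored; their count is returned
    and at least ``min_coverage`` of the aneuploid-chromosome genes must
    carry a value.
    """
    if method not in ("surplus", "dosage"):
        raise ValidationError(f"unknown load method {method!r}")
    aneu = karyotype.aneuploid_chromosomes
    if not aneu:
        return 0.0, 0
    if "copies_per_cell" not in annotation.columns:
        raise ValidationError("annotation lacks copies_per_cell")
    sub = annotation[annotation["chromosome"].isin(aneu)]
    copies = pd.to_numeric(sub["copies_per_cell"], errors="coerce")
    n_missing = int(copies.isna().sum())
    if len(sub) and copies.notna().mean() < min_coverage:
        raise ValidationError(
            f"copies_per_cell covers under {min_coverage:.0%} of aneuploid genes"
        )
    load = 0.0
    for chrom in aneu:
        weight = karyotype.chrom_cn[chrom] / karyotype.ploidy
        weight = abs(weight - 1.0) if method == "surplus" else weight
        chrom_copies = copies[sub["chromosome"] == chrom].dropna()
        load += float(chrom_copies.sum()) * weight
    return load, n_missing
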