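"""Relative-dosage integration of karyotypes with expression layers.

Builds the integrated dataset the attenuation statistics run on: relative
chromosome copy-number changes log2(CN/ploidy), gene-wise log2 expression
ratios against the euploid reference median, strain-wise trans
normalization (per-strain euploid-chromosome median forced to 0), and the
±4 SD chromosome-vs-mRNA consistency filter with the two-pass
recomputation after exclusions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    Karyotype,
    Parameters,
    RelativeMatrix,
    ValidationError,
    gene_chromosomes,
)

log = logging.getLogger("dosagecomp")

#: minimum euploid reference values required per gene (paper silent; conservative)
MIN_REFERENCE_VALUES = 3


def relative_cn(karyotype: Karyotype) -> dict[str, float]:
    """log2(chromosome copy number / ploidy); 0 on euploid chromosomes."""
    return karyotype.relative_cn()


def relative_cn_table(karyotypes: list[Karyotype]) -> pd.DataFrame:
    """Strain x chromosome table of relative CN changes."""
    table = pd.DataFrame({k.strain_id: k.relative_cn() for k in karyotypes}).T
    table.index.name = "strain_id"
    return table


def relative_expression(matrix: ExpressionMatrix, karyotypes: list[Karyotype],
                        method: str = "all_euploid",
                        min_reference: int = MIN_REFERENCE_VALUES) -> RelativeMatrix:
    """log2 ratios of each gene against the euploid reference median.

    ``all_euploid``: the reference is the per-gene median over all euploid
    strains.  ``ploidy_wise``: each strain is compared to euploid strains
    of its own basal ploidy.  Reference medians ignore missing values;
    genes with fewer than ``min_reference`` euploid values get an
    all-missing row (reported in the log).
    """
    strains = [k.strain_id for k in karyotypes if k.strain_id in matrix.values.columns]
    values = matrix.values[strains]
    by_id = {k.strain_id: k for k in karyotypes}

    def reference_for(cols: list[str]) -> pd.Series:
        ref_values = values[cols]
        counts = ref_values.notna().sum(axis=1)
        ref = ref_values.median(axis=1, skipna=True)
        ref[counts < min_reference] = np.nan
        return ref

    ratios = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    if method == "all_euploid":
        euploid = [s for s in strains if by_id[s].is_euploid]
        if not euploid:
            raise ValidationError("no euploid strains for reference")
        ref = reference_for(euploid)
        ratios.loc[:, :] = np.log2(values.div(ref, axis=0)).to_numpy()
    elif method == "ploidy_wise":
        for ploidy in sorted({by_id[s].ploidy for s in strains}):
            group = [s for s in strains if by_id[s].ploidy == ploidy]
            euploid = [s for s in group if by_id[s].is_euploid]
            if not euploid:
                raise ValidationError(
                    f"ploidy {ploidy} has no euploid reference strains"
                )
            ref = reference_for(euploid)
            ratios[group] = np.log2(values[group].div(ref, axis=0))
    else:
        raise ValidationError(f"unknown reference method {method!r}")
    n_dropped = int(ratios.isna().all(axis=1).sum())
    if n_dropped:
        log.info(
            "%s layer: %d genes lack a euploid reference (>= %d values) "
            "and have all-missing relative rows",
            matrix.layer, n_dropped, min_reference,
        )
    return RelativeMatrix(matrix.layer, ratios, reference_method=method,
                          normalized=False)


def normalize_trans(rel: RelativeMatrix, karyotypes: list[Karyotype],
                    annotation: pd.DataFrame) -> RelativeMatrix:
    """Subtract each strain's median ratio over genes on euploid chromosomes.

    After normalization the per-strain euploid-chromosome median is exactly
    0, so trans shifts cannot masquerade as cis dosage effects.  Idempotent.
    """
    chroms = gene_chromosomes(annotation, rel.values.index)
    by_id = {k.strain_id: k for k in karyotypes}
    out = rel.values.copy()
    for strain in rel.values.columns:
        kary = by_id[strain]
        euploid_chroms = {
            c for c, cn in kary.chrom_cn.items() if cn == kary.ploidy
        }
        if not euploid_chroms:
            raise ValidationError(
                f"strain {strain!r} has no euploid chromosome to normalize against"
            )
        mask = chroms.isin(euploid_chroms).to_numpy()
        col = rel.values[strain].to_numpy()
        ref = col[mask]
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            raise ValidationError(
                f"strain {strain!r} has no present values on euploid chromosomes"
            )
        out[strain] = col - np.median(ref)
    return RelativeMatrix(rel.layer, out, reference_method=rel.reference_method,
                          normalized=True)


def flag_cn_mrna_mismatch(cn_table: pd.DataFrame, rel_mrna: RelativeMatrix,
                          annotation: pd.DataFrame,
                          mismatch_sd: float = 4.0) -> tuple[list[str], pd.DataFrame]:
    """Flag strains whose karyotype disagrees with their transcriptome.

    For every (strain, chromosome) pair, d = relative CN change minus the
    median normalized mRNA ratio on that chromosome; all pairs are pooled
    and a strain is flagged iff any of its pairs deviates from the pooled
    mean by more than ``mismatch_sd`` standard deviations.  A degenerate
    pooled sd of 0 flags nothing.

    Returns the flagged strains and the per-pair d table.
    """
    strains = [s for s in cn_table.index if s in rel_mrna.values.columns]
    chroms = gene_chromosomes(annotation, rel_mrna.values.index)
    records = []
    for strain in strains:
        col = rel_mrna.values[strain]
        chrom_medians = col.groupby(chroms.to_numpy()).median()
        for chrom in cn_table.columns:
            med = chrom_medians.get(chrom, np.nan)
            if not np.isfinite(med):
                continue
            records.append(
                {"strain_id": strain, "chromosome": chrom,
                 "d": float(cn_table.at[strain, chrom]) - float(med)}
            )
    pairs = pd.DataFrame(records)
    if len(pairs) < 2:
        raise ValidationError("mismatch filter needs >= 2 strain-chromosome pairs")
    mean_d = pairs["d"].mean()
    sd_d = pairs["d"].std(ddof=1)
    # sd below numerical noise (log2 units) counts as degenerate: the pairs
    # only "differ" at floating-point epsilon scale
    if sd_d <= 1e-9:
        log.info("mismatch filter: degenerate sd=%.3g, flagging nothing", sd_d)
        pairs["flagged"] = False
        return [], pairs
    pairs["z"] = (pairs["d"] - mean_d) / sd_d
    pairs["flagged"] = pairs["z"].abs() > mismatch_sd
    flagged = sorted(pairs.loc[pairs["flagged"], "strain_id"].unique())
    if flagged:
        log.info("mismatch filter: flagged strains %s", flagged)
    return flagged, pairs


@dataclass
class IntegratedCohort:
    """Integrated relative-dosage dataset over the shared strain/gene index."""

    karyotypes: list[Karyotype]
    cn: pd.DataFrame                      # strain x chromosome relative CN
    layers: dict[str, RelativeMatrix]     # normalized relative matrices
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["strain_id", "reason"])
    )

    def karyotype(self, strain_id: str) -> Karyotype:
        for k in self.karyotypes:
            if k.strain_id == strain_id:
                return k
        raise KeyError(strain_id)


def build_integrated_cohort(layers: dict[str, ExpressionMatrix],
                            karyotypes: list[Karyotype],
                            annotation: pd.DataFrame,
                            params: Parameters | None = None,
                            method: str = "all_euploid",
                            exclude: dict[str, str] | None = None) -> IntegratedCohort:
    """Two-pass integration driver.

    Pass 1 computes relative, trans-normalized matrices on the shared
    gene/strain index and applies the CN-mRNA mismatch filter; pass 2
    recomputes everything without the excluded strains, so the euploid
    reference is not biased by them.  ``exclude`` allows manual exclusions
    (strain -> reason) before pass 1.
    """
    params = params or Parameters()
    exclusions: dict[str, str] = dict(exclude or {})

    def assemble(excluded: dict[str, str]) -> IntegratedCohort:
        keep_k = [k for k in karyotypes if k.strain_id not in excluded]
        shared_strains = set(k.strain_id for k in keep_k)
        shared_genes: pd.Index | None = None
        for mat in layers.values():
            shared_strains &= set(mat.values.columns)
            genes = mat.values.index.intersection(annotation.index)
            shared_genes = genes if shared_genes is None else shared_genes.intersection(genes)
        keep_k = [k for k in keep_k if k.strain_id in shared_strains]
        strain_order = [k.strain_id for k in keep_k]
        rel_layers = {}
        for name, mat in layers.items():
            sub = ExpressionMatrix(
                mat.layer, mat.values.loc[shared_genes, strain_order],
            )
            rel = relative_expression(sub, keep_k, method=method)
            rel_layers[name] = normalize_trans(rel, keep_k, annotation)
        cn = relative_cn_table(keep_k)
        excluded_df = pd.DataFrame(
            [{"strain_id": s, "reason": r} for s, r in sorted(excluded.items())]
        )
        if excluded_df.empty:
            excluded_df = pd.DataFrame(columns=["strain_id", "reason"])
        return IntegratedCohort(keep_k, cn, rel_layers, excluded_df)

    first = assemble(exclusions)
    if "mRNA" in first.layers:
        flagged, _ = flag_cn_mrna_mismatch(
            first.cn, first.layers["mRNA"], annotation,
            mismatch_sd=params.mismatch_sd,
        )
        for strain in flagged:
            exclusions[strain] = "mismatch"
        if flagged:
            return assemble(exclusions)
    return first
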