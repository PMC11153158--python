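"""Gene-by-gene dosage-compensation quantification.

Each gene's attenuation slope is the linear-regression coefficient of its
normalized log2 expression ratio on the relative chromosome copy-number
change across strains: slope 1 means expression follows gene dosage
(y = x), slope 0 full compensation, and attenuation % = 100 (1 - slope).
Natural-cohort fits include an intercept and require the gene to be
aneuploid in at least ``min_aneuploid_points`` isolates; disome-collection
fits have a single aneuploid point per gene and are forced through the
origin.  Chromosome losses (negative CN change) are excluded by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    Karyotype,
    RelativeMatrix,
    ValidationError,
    gene_chromosomes,
)
from .stats import bh_adjust, mannwhitney_auc, ols_through_origin, spearman_exact

log = logging.getLogger("dosagecomp")


def fit_gene_slopes(rel: RelativeMatrix, cn_table: pd.DataFrame,
                    karyotypes: list[Karyotype], annotation: pd.DataFrame,
                    mode: str = "natural", min_aneuploid_points: int = 3,
                    attenuation_threshold: float = 0.85,
                    include_losses: bool = False) -> pd.DataFrame:
    """Per-gene dosage-response regressions against relative CN change.

    Points are (Delta_cn, log2 ratio) over non-reverted strains with a
    present value and Delta_cn >= 0 (losses excluded unless requested).
    Returns a gene-indexed table with slope, intercept, point counts,
    attenuation %, and the attenuated flag at ``attenuation_threshold``.
    """
    if mode not in ("natural", "disome"):
        raise ValidationError(f"unknown fit mode {mode!r}")
    keep = [
        k.strain_id for k in karyotypes
        if not k.reverted and k.strain_id in rel.values.columns
    ]
    n_reverted = sum(bool(k.reverted) for k in karyotypes)
    if n_reverted:
        log.info("gene fits: excluding %d reverted strains", n_reverted)
    values = rel.values[keep].to_numpy(dtype=float)
    if np.any(np.isinf(values)):
        raise ValidationError("relative matrix contains non-finite values")
    chroms = gene_chromosomes(annotation, rel.values.index)
    delta = cn_table.loc[keep]  # strain x chromosome

    records = []
    min_aneu = 1 if mode == "disome" else min_aneuploid_points
    for gi, gene in enumerate(rel.values.index):
        chrom = chroms.iloc[gi]
        if chrom not in delta.columns:
            continue
        x = delta[chrom].to_numpy(dtype=float)
        y = values[gi]
        mask = np.isfinite(y)
        if not include_losses:
            mask &= x >= 0
        x_use, y_use = x[mask], y[mask]
        n_aneu = int(np.sum(x_use != 0))
        if n_aneu < min_aneu or x_use.size < 2:
            continue
        if mode == "natural":
            if np.allclose(x_use, x_use[0]):
                continue
            slope, intercept = np.polyfit(x_use, y_use, 1)
        else:
            slope = ols_through_origin(x_use, y_use)
            intercept = 0.0
        records.append(
            {
                "gene_id": gene,
                "layer": rel.layer,
                "slope": float(slope),
                "intercept": float(intercept),
                "n_points_total": int(x_use.size),
                "n_aneuploid_points": n_aneu,
                "attenuation_pct": 100.0 * (1.0 - float(slope)),
                "attenuated": bool(slope < attenuation_threshold),
                "mode": mode,
            }
        )
    if not records:
        log.warning("gene fits: no gene had enough aneuploid points")
        return pd.DataFrame(
            columns=["gene_id", "layer", "slope", "intercept", "n_points_total",
                     "n_aneuploid_points", "attenuation_pct", "attenuated",
                     "mode"]
        ).set_index("gene_id")
    return pd.DataFrame(records).set_index("gene_id")


def rolling_threshold(slopes: pd.Series, grid) -> pd.DataFrame:
    """Cumulative attenuation analysis over a threshold grid.

    For each threshold: the fraction of genes with slope below it and the
    median slope among those (the effect size); the fraction is a
    non-decreasing step function of the threshold.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("rolling_threshold needs a non-empty grid")
    s = np.asarray(slopes, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValidationError("rolling_threshold needs at least one slope")
    rows = []
    for thr in grid:
        below = s[s < thr]
        rows.append(
            {
                "threshold": float(thr),
                "n_below": int(below.size),
                "fraction_attenuated": below.size / s.size,
                "median_effect": float(np.median(below)) if below.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def compare_layers(mrna_slopes: pd.Series, protein_slopes: pd.Series) -> dict:
    """Pair mRNA and protein slopes per gene; Spearman rank correlation.

    Exact permutation p for n <= 8 (test-scale), the standard asymptotic
    p otherwise.  Also reports the per-layer median slopes.
    """
    paired = pd.DataFrame(
        {"mrna": mrna_slopes, "protein": protein_slopes}
    ).dropna()
    n = len(paired)
    if n < 3:
        raise ValidationError("layer comparison needs >= 3 shared genes")
    if n <= 8:
        rho, p = spearman_exact(paired["mrna"], paired["protein"])
    else:
        res = sps.spearmanr(paired["mrna"], paired["protein"])
        rho, p = float(res.statistic), float(res.pvalue)
    return {
        "n_genes": n,
        "spearman_rho": rho,
        "p_value": p,
        "median_mrna_slope": float(paired["mrna"].median()),
        "median_protein_slope": float(paired["protein"].median()),
        "paired": paired,
    }


def property_association(slopes: pd.DataFrame,
                         properties: pd.DataFrame) -> pd.DataFrame:
    """Compare gene properties between attenuated and non-attenuated genes.

    For every property column: a two-sample two-sided Wilcoxon
    (Mann–Whitney) test plus the rank-based AUC = U/(n1 n2), with BH
    adjustment across the property family.  ``slopes`` must carry the
    ``attenuated`` flag from :func:`fit_gene_slopes`.
    """
    shared = slopes.index.intersection(properties.index)
    att_flag = slopes.loc[shared, "attenuated"].astype(bool)
    if att_flag.nunique() < 2:
        raise ValidationError("both attenuated and non-attenuated genes required")
    rows = []
    for prop in properties.columns:
        vals = pd.to_numeric(properties.loc[shared, prop], errors="coerce")
        ok = vals.notna()
        x = vals[ok & att_flag]
        y = vals[ok & ~att_flag]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(
                f"property {prop!r}: need >= 2 genes per class"
            )
        auc, p = mannwhitney_auc(x, y)
        rows.append(
            {
                "property": prop,
                "n_attenuated": int(len(x)),
                "n_not_attenuated": int(len(y)),
                "median_attenuated": float(np.median(x)),
                "median_not_attenuated": float(np.median(y)),
                "auc_attenuated_higher": auc,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows).set_index("property")
    out["p_adj"] = bh_adjust(out["p_raw"])
    return out


def cross_collection_overlap(natural: pd.DataFrame, disome: pd.DataFrame) -> dict:
    """2x2 contingency of attenuated status between the two collections."""
    shared = natural.index.intersection(disome.index)
    if len(shared) < 1:
        raise ValidationError("no shared genes between collections")
    nat = natural.loc[shared, "attenuated"].astype(bool)
    dis = disome.loc[shared, "attenuated"].astype(bool)
    both = int((nat & dis).sum())
    nat_only = int((nat & ~dis).sum())
    dis_only = int((~nat & dis).sum())
    neither = int((~nat & ~dis).sum())
    n_dis = both + dis_only
    return {
        "n_shared": int(len(shared)),
        "attenuated_in_both": both,
        "natural_only": nat_only,
        "disome_only": dis_only,
        "neither": neither,
        "fraction_disome_attenuated_also_natural": both / n_dis if n_dis else np.nan,
    }
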