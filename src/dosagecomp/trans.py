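"""Trans-response quantification on euploid chromosomes of aneuploid strains.

"Trans" expression is the behaviour of genes that are *not* on an
aneuploid chromosome of a given aneuploid strain; cis entries are masked
before any statistic is computed.  Per-gene medians feed signature /
enrichment analyses downstream; per-gene one-sample t-tests against mu=0
with BH adjustment give the volcano; Pearson correlations relate gene-set
summaries (e.g. mean proteasome induction) to per-strain covariates such
as the aneuploid protein load or RPN4 transcript level.
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
from .stats import bh_adjust

log = logging.getLogger("dosagecomp")


def trans_matrix(rel: RelativeMatrix, karyotypes: list[Karyotype],
                 annotation: pd.DataFrame,
                 gene_set: str | None = None,
                 strains: list[str] | None = None) -> pd.DataFrame:
    """Gene x aneuploid-strain matrix with cis entries masked to NaN.

    Entry (g, s) is retained iff gene g's chromosome is euploid in strain
    s and the value is present.  ``gene_set`` optionally restricts rows to
    genes carrying that label in ``annotation.gene_sets``.  Requesting a
    euploid strain is an error — trans response is defined for aneuploids.
    """
    by_id = {k.strain_id: k for k in karyotypes}
    if strains is None:
        strains = [
            k.strain_id for k in karyotypes
            if not k.is_euploid and k.strain_id in rel.values.columns
        ]
    if not strains:
        raise ValidationError("trans matrix needs at least one aneuploid strain")
    for s in strains:
        if by_id[s].is_euploid:
            raise ValidationError(
                f"strain {s!r} is euploid; trans response is defined for aneuploids"
            )
    genes = rel.values.index
    if gene_set is not None:
        in_set = annotation.loc[genes, "gene_sets"].map(lambda gs: gene_set in gs)
        genes = genes[in_set.to_numpy()]
    chroms = gene_chromosomes(annotation, genes)
    out = rel.values.loc[genes, strains].copy()
    for s in strains:
        aneu = set(by_id[s].aneuploid_chromosomes)
        cis = chroms.isin(aneu).to_numpy()
        out.loc[cis, s] = np.nan
    return out


def trans_medians(tmatrix: pd.DataFrame, min_support: int = 3) -> pd.DataFrame:
    """Per-gene median trans log2 ratio with a low-support flag.

    Genes with no present value are absent from the output; genes with
    fewer than ``min_support`` contributing strains are flagged.
    """
    n = tmatrix.notna().sum(axis=1)
    med = tmatrix.median(axis=1, skipna=True)
    out = pd.DataFrame(
        {"median_log2_ratio": med, "n_strains": n, "low_support": n < min_support}
    )
    return out[n > 0]


def trans_ttests(tmatrix: pd.DataFrame, alpha: float = 0.05,
                 min_strains: int = 3) -> pd.DataFrame:
    """Per-gene one-sample t-test of mean trans log2 ratio against mu = 0.

    Classical t with df = n - 1; genes with n < ``min_strains`` or zero
    variance are skipped with a warning.  BH adjustment spans all tested
    genes of the layer; ``significant`` means p_adj < ``alpha``.
    """
    rows = []
    n_skipped = 0
    for gene, row in tmatrix.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size < min_strains or np.std(vals, ddof=1) == 0:
            n_skipped += 1
            continue
        res = sps.ttest_1samp(vals, popmean=0.0)
        rows.append(
            {
                "gene_id": gene,
                "n_strains_used": int(vals.size),
                "mean_log2_ratio": float(vals.mean()),
                "t_stat": float(res.statistic),
                "p_raw": float(res.pvalue),
            }
        )
    if n_skipped:
        log.warning("trans t-tests: skipped %d genes (too few strains or zero variance)",
                    n_skipped)
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "n_strains_used", "mean_log2_ratio", "t_stat",
                     "p_raw", "p_adj", "significant"]
        ).set_index("gene_id")
    out = pd.DataFrame(rows).set_index("gene_id")
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] < alpha
    return out


def covariate_correlation(summary: pd.Series, covariate: pd.Series) -> dict:
    """Pearson correlation between a per-strain summary and a covariate."""
    paired = pd.DataFrame({"x": summary, "y": covariate}).dropna()
    if len(paired) < 3:
        raise ValidationError("covariate correlation needs >= 3 strains")
    if paired["y"].std(ddof=1) == 0 or paired["x"].std(ddof=1) == 0:
        raise ValidationError("zero-variance input to covariate correlation")
    res = sps.pearsonr(paired["x"], paired["y"])
    return {"r": float(res.statistic), "p_value": float(res.pvalue),
            "n_strains": int(len(paired))}
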