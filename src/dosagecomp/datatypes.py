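"""Shared domain types for the dosage-compensation pipeline.

Conventions used throughout the package:

* matrices are genes-as-rows, strains-as-columns pandas DataFrames;
* all expression logs are base 2; natural log appears only inside the
  turnover kinetics (documented there);
* missing values are explicit ``NaN`` entries, never sentinel numbers;
* chromosome labels are opaque strings, gene order within a chromosome is
  an ordinal ``position_index`` (the analysis never needs coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "protein", "ubiquitin", "precursor")

#: gene-set labels understood by the trans-response machinery
GENE_SET_LABELS = (
    "ESR_up",
    "ESR_down",
    "CAGE_up",
    "CAGE_down",
    "APS_up",
    "proteasome",
    "arbitrary",
)

ANNOTATION_COLUMNS = (
    "chromosome",
    "position_index",
    "complex_member",
    "reference_half_life",
    "copies_per_cell",
    "gene_sets",
)


class ValidationError(ValueError):
    """Raised when an input table violates a documented contract."""


@dataclass
class Karyotype:
    """Per-strain basal ploidy and integer chromosome copy numbers.

    A strain is euploid iff every chromosome copy number equals the basal
    ploidy.  ``reverted`` is set downstream by
    :func:`dosagecomp.strains.detect_reverted` once protein-level
    pseudomedians are available.
    """

    strain_id: str
    ploidy: int
    chrom_cn: dict[str, int]
    reverted: bool | None = None

    def __post_init__(self) -> None:
        if not (1 <= int(self.ploidy) <= 5):
            raise ValidationError(
                f"strain {self.strain_id!r}: ploidy must be in [1, 5], got {self.ploidy}"
            )
        self.ploidy = int(self.ploidy)
        clean: dict[str, int] = {}
        for chrom, cn in self.chrom_cn.items():
            if float(cn) != int(cn) or int(cn) < 1:
                raise ValidationError(
                    f"strain {self.strain_id!r}, chromosome {chrom!r}: "
                    f"copy number must be an integer >= 1, got {cn!r}"
                )
            clean[str(chrom)] = int(cn)
        self.chrom_cn = clean

    @property
    def is_euploid(self) -> bool:
        return all(cn == self.ploidy for cn in self.chrom_cn.values())

    @property
    def aneuploid_chromosomes(self) -> list[str]:
        return [c for c, cn in self.chrom_cn.items() if cn != self.ploidy]

    def relative_cn(self) -> dict[str, float]:
        """log2(copy number / ploidy) per chromosome; 0 for euploid ones."""
        return {
            c: float(np.log2(cn / self.ploidy)) for c, cn in self.chrom_cn.items()
        }


@dataclass
class ExpressionMatrix:
    """Gene x strain positive abundances on one omics layer.

    ``values`` holds linear-scale abundances with ``NaN`` for missing
    entries; present values must be strictly positive.  ``strain_meta``
    optionally carries a ``batch`` label and ``is_qc`` flag per column.
    """

    layer: str
    values: pd.DataFrame
    strain_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene rows: {list(dupes)[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr[np.isfinite(arr)] <= 0):
            raise ValidationError(
                f"{self.layer} matrix contains non-positive present values; "
                "zeros must be recorded as missing"
            )
        if self.strain_meta is not None:
            missing = self.values.columns.difference(self.strain_meta.index)
            if len(missing):
                raise ValidationError(
                    f"strain_meta lacks entries for samples {list(missing)[:5]}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def strains(self) -> pd.Index:
        return self.values.columns


@dataclass
class RelativeMatrix:
    """Gene x strain log2 ratios versus a euploid reference."""

    layer: str
    values: pd.DataFrame
    reference_method: str = "all_euploid"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if self.reference_method not in ("all_euploid", "ploidy_wise"):
            raise ValidationError(
                f"unknown reference_method {self.reference_method!r}"
            )


@dataclass
class Parameters:
    """Single source of truth for every analysis cutoff.

    Defaults are the study's printed constants: the 0.85 attenuation-slope
    threshold, the ±4 SD copy-number/mRNA mismatch rule, the (−0.1, 0.1)
    reversion band, 80% presence, CV < 0.3 in QC samples, the 2.5-SD sample
    outlier rule, the 300/50 gain/loss distribution cutoffs, the 0.8 log2
    chromosome-duplication call, and the ≥3-occurrence turnover-context rule.
    """

    attenuation_threshold: float = 0.85
    min_aneuploid_points: int = 3
    mismatch_sd: float = 4.0
    reversion_band: tuple[float, float] = (-0.1, 0.1)
    presence_fraction: float = 0.8
    qc_cv_max: float = 0.3
    outlier_z: float = 2.5
    gains_min_genes: int = 300
    losses_min_genes: int = 50
    duplication_log2_threshold: float = 0.8
    knn_k: int = 10
    min_context_occurrences: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.reversion_band = tuple(self.reversion_band)  # type: ignore[assignment]
        if not 0 < self.attenuation_threshold <= 2:
            raise ValidationError("attenuation_threshold outside (0, 2]")
        if self.min_aneuploid_points < 1:
            raise ValidationError("min_aneuploid_points must be >= 1")
        if self.mismatch_sd <= 0 or self.outlier_z <= 0:
            raise ValidationError("SD thresholds must be positive")
        lo, hi = self.reversion_band
        if not lo < hi:
            raise ValidationError("reversion_band must be an increasing pair")
        if not 0 < self.presence_fraction <= 1:
            raise ValidationError("presence_fraction outside (0, 1]")
        if self.qc_cv_max <= 0:
            raise ValidationError("qc_cv_max must be positive")
        if self.gains_min_genes < 0 or self.losses_min_genes < 0:
            raise ValidationError("distribution cutoffs must be non-negative")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.min_context_occurrences < 1:
            raise ValidationError("min_context_occurrences must be >= 1")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.field_names()}


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (indexed by ``gene_id``).

    Required columns: ``chromosome`` and ``position_index``; optional:
    ``complex_member``, ``reference_half_life``, ``copies_per_cell`` and
    ``gene_sets`` (a frozenset of labels per gene).  ``gene_id`` must be
    unique, as must ``position_index`` within each chromosome.
    """
    for col in ("chromosome", "position_index"):
        if col not in annotation.columns:
            raise ValidationError(f"annotation lacks required column {col!r}")
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique()
        raise ValidationError(f"duplicate gene_id in annotation: {list(dupes)[:5]}")
    pos = annotation["position_index"]
    if (pos < 0).any() or (pos.astype(float) != pos.astype(int)).any():
        raise ValidationError("position_index must be integers >= 0")
    dup_pos = annotation.duplicated(subset=["chromosome", "position_index"])
    if dup_pos.any():
        raise ValidationError(
            "position_index must be unique within a chromosome; offending genes: "
            f"{list(annotation.index[dup_pos])[:5]}"
        )
    out = annotation.copy()
    if "complex_member" not in out.columns:
        out["complex_member"] = False
    out["complex_member"] = out["complex_member"].astype(bool)
    if "gene_sets" not in out.columns:
        out["gene_sets"] = [frozenset()] * len(out)
    else:
        out["gene_sets"] = [
            s if isinstance(s, frozenset) else frozenset(s) if s else frozenset()
            for s in out["gene_sets"]
        ]
    return out


def gene_chromosomes(annotation: pd.DataFrame, genes) -> pd.Series:
    """Chromosome label per gene, restricted and ordered to ``genes``."""
    missing = pd.Index(genes).difference(annotation.index)
    if len(missing):
        raise ValidationError(
            f"genes absent from annotation: {list(missing)[:5]}"
        )
    return annotation.loc[genes, "chromosome"]


def karyotype_frame(karyotypes: list[Karyotype]) -> pd.DataFrame:
    """Strain x chromosome integer copy-number table plus a ploidy column."""
    rows = {k.strain_id: dict(k.chrom_cn, ploidy=k.ploidy) for k in karyotypes}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "strain_id"
    return df
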