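"""Synthetic aneuploid-cohort generator with ground truth.

The generator emulates the statistical structure the analysis assumes for
a natural yeast cohort: strains of basal ploidy 1-5 with ~15% aneuploids
(gains dominating losses 88.4%/11.6%), mRNA scaling ~1:1 with relative
chromosome copy number, protein dosage-response slopes drawn from a
mixture (complex members biased towards the attenuated component),
log-normal baseline abundances, independent log2 noise per layer,
missingness, optional batch shifts, a trans proteasome induction in
aneuploid strains, and exponential SILAC labelling kinetics.

The dosage model per gene g on chromosome c in strain s is

    log2 ratio = slope_g * Delta_cs + noise,   Delta_cs = log2(CN_cs / ploidy_s)

so a non-buffered gene has slope 1 (y = x) and a fully compensated gene
slope 0.  Ground-truth slopes, karyotypes and per-strain attenuation are
returned for every cohort so downstream estimates can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, Karyotype, ValidationError

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_silac",
    "simulate_precursors",
]


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the natural-isolate cohort the analysis targets:
    613-strain-like ploidy composition (mostly diploid), 15% aneuploid
    strains, 88.4% of aneuploid events being gains, 27% of aneuploid
    strains carrying a second aneuploid chromosome, a protein-slope
    mixture putting ~70% of genes below the 0.85 attenuation threshold,
    0.2 log2 residual noise per layer, and 4% missing values.
    """

    n_strains: int = 200
    n_chromosomes: int = 16
    genes_per_chromosome: int = 94
    ploidy_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.60, 3: 0.08, 4: 0.04, 5: 0.03}
    )
    aneuploidy_rate: float = 0.15
    gain_fraction: float = 0.884
    complex_aneuploidy_rate: float = 0.27
    mrna_slope_mean: float = 1.0
    mrna_slope_sd: float = 0.05
    #: (weight, mean, sd) components; first component is the attenuated one
    protein_slope_mixture: tuple[tuple[float, float, float], ...] = (
        (0.704, 0.50, 0.15),
        (0.296, 1.00, 0.05),
    )
    complex_member_rate: float = 0.30
    complex_low_bias: float = 0.20
    mrna_noise_sd: float = 0.2
    protein_noise_sd: float = 0.2
    trans_proteasome_shift: float = 0.3
    n_proteasome_genes: int = 30
    missing_rate: float = 0.04
    n_batches: int = 1
    batch_shift_sd: float = 0.3
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.ploidy_weights.values())
        if not np.isclose(total, 1.0):
            raise ValidationError("ploidy_weights must sum to 1")
        for name in ("aneuploidy_rate", "gain_fraction", "complex_aneuploidy_rate",
                     "missing_rate"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {val}")
        wsum = sum(w for w, _, _ in self.protein_slope_mixture)
        if not np.isclose(wsum, 1.0):
            raise ValidationError("protein_slope_mixture weights must sum to 1")
        if self.aneuploidy_rate > 0 and self.n_chromosomes == 0:
            raise ValidationError("aneuploidy_rate > 0 requires chromosomes")


@dataclass
class GroundTruth:
    """True parameters aligned to generated gene/strain ids."""

    genes: pd.DataFrame      # mrna_slope, protein_slope, complex_member, proteasome
    strains: pd.DataFrame    # ploidy, aneuploid flag, true_attenuation_pct, batch


@dataclass
class SimulatedCohort:
    annotation: pd.DataFrame
    karyotypes: list[Karyotype]
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    truth: GroundTruth
    spec: CohortSpec


def _draw_karyotypes(spec: CohortSpec, chroms: list[str],
                     rng: np.random.Generator) -> list[Karyotype]:
    ploidies = list(spec.ploidy_weights)
    weights = np.array([spec.ploidy_weights[p] for p in ploidies], dtype=float)
    karyotypes = []
    for i in range(spec.n_strains):
        sid = f"S{i + 1:04d}"
        ploidy = int(rng.choice(ploidies, p=weights))
        cn = {c: ploidy for c in chroms}
        if rng.random() < spec.aneuploidy_rate:
            n_events = 1 + (rng.random() < spec.complex_aneuploidy_rate)
            hit = rng.choice(len(chroms), size=n_events, replace=False)
            for idx in hit:
                gain = rng.random() < spec.gain_fraction or ploidy == 1
                cn[chroms[idx]] = ploidy + 1 if gain else ploidy - 1
        karyotypes.append(Karyotype(strain_id=sid, ploidy=ploidy, chrom_cn=cn))
    return karyotypes


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate annotation, karyotypes, mRNA/protein matrices and ground truth.

    Identical spec (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1:02d}" for i in range(spec.n_chromosomes)]
    n_genes = spec.n_chromosomes * spec.genes_per_chromosome
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]

    annotation = pd.DataFrame(
        {
            "chromosome": np.repeat(chroms, spec.genes_per_chromosome),
            "position_index": np.tile(
                np.arange(spec.genes_per_chromosome), spec.n_chromosomes
            ),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    annotation["complex_member"] = rng.random(n_genes) < spec.complex_member_rate
    proteasome_idx = rng.choice(
        n_genes, size=min(spec.n_proteasome_genes, n_genes), replace=False
    )
    is_proteasome = np.zeros(n_genes, dtype=bool)
    is_proteasome[proteasome_idx] = True
    annotation["gene_sets"] = [
        frozenset(["proteasome"]) if flag else frozenset() for flag in is_proteasome
    ]

    karyotypes = _draw_karyotypes(spec, chroms, rng)
    strain_ids = [k.strain_id for k in karyotypes]

    # true dosage-response slopes
    mrna_slope = rng.normal(spec.mrna_slope_mean, spec.mrna_slope_sd, n_genes)
    weights = np.array([w for w, _, _ in spec.protein_slope_mixture])
    low_w = weights[0]
    # complex members are biased to the attenuated (first) component; the
    # non-complex probability compensates so the marginal stays at low_w
    p_low_complex = float(np.clip(low_w + spec.complex_low_bias, 0, 1))
    rate = spec.complex_member_rate
    p_low_other = float(np.clip(
        (low_w - rate * p_low_complex) / max(1 - rate, 1e-12), 0, 1
    ))
    p_low = np.where(
        annotation["complex_member"].to_numpy(), p_low_complex, p_low_other
    )
    if len(weights) == 1:
        comp = np.zeros(n_genes, dtype=int)
    else:
        rest = 1 + rng.choice(
            len(weights) - 1, size=n_genes, p=weights[1:] / weights[1:].sum()
        )
        comp = np.where(rng.random(n_genes) < p_low, 0, rest)
    means = np.array([m for _, m, _ in spec.protein_slope_mixture])
    sds = np.array([s for _, _, s in spec.protein_slope_mixture])
    protein_slope = np.clip(
        rng.normal(means[comp], sds[comp]), 0.0, None
    )

    # relative CN change per (chromosome, strain)
    delta = pd.DataFrame(
        {k.strain_id: k.relative_cn() for k in karyotypes}
    ).loc[chroms]
    delta_genes = delta.reindex(annotation["chromosome"]).to_numpy()  # genes x strains

    aneuploid = np.array([not k.is_euploid for k in karyotypes])
    mrna_log2 = mrna_slope[:, None] * delta_genes
    protein_log2 = protein_slope[:, None] * delta_genes
    if spec.trans_proteasome_shift:
        protein_log2 = protein_log2 + (
            spec.trans_proteasome_shift
            * np.outer(is_proteasome, aneuploid.astype(float))
        )
    if spec.mrna_noise_sd:
        mrna_log2 = mrna_log2 + rng.normal(0, spec.mrna_noise_sd, mrna_log2.shape)
    if spec.protein_noise_sd:
        protein_log2 = protein_log2 + rng.normal(
            0, spec.protein_noise_sd, protein_log2.shape
        )

    baseline_m = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_genes)
    baseline_p = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, n_genes)

    batch = pd.Series(
        [f"B{(i % spec.n_batches) + 1}" for i in range(spec.n_strains)],
        index=strain_ids, name="batch",
    )
    batch_effect = np.zeros(spec.n_strains)
    if spec.n_batches > 1 and spec.batch_shift_sd:
        shifts = rng.normal(0, spec.batch_shift_sd, spec.n_batches)
        batch_effect = shifts[[i % spec.n_batches for i in range(spec.n_strains)]]

    mrna_abs = 2.0 ** (baseline_m[:, None] + mrna_log2 + batch_effect[None, :])
    prot_abs = 2.0 ** (baseline_p[:, None] + protein_log2 + batch_effect[None, :])

    if spec.missing_rate:
        mrna_abs = np.where(
            rng.random(mrna_abs.shape) < spec.missing_rate, np.nan, mrna_abs
        )
        prot_abs = np.where(
            rng.random(prot_abs.shape) < spec.missing_rate, np.nan, prot_abs
        )

    gene_index = pd.Index(genes, name="gene_id")
    mrna = ExpressionMatrix(
        "mRNA", pd.DataFrame(mrna_abs, index=gene_index, columns=strain_ids)
    )
    meta = pd.DataFrame({"batch": batch, "is_qc": False})
    protein = ExpressionMatrix(
        "protein",
        pd.DataFrame(prot_abs, index=gene_index, columns=strain_ids),
        strain_meta=meta,
    )

    truth_genes = pd.DataFrame(
        {
            "chromosome": annotation["chromosome"],
            "mrna_slope": mrna_slope,
            "protein_slope": protein_slope,
            "complex_member": annotation["complex_member"],
            "proteasome": is_proteasome,
        },
        index=gene_index,
    )
    truth_strains = _strain_truth(karyotypes, truth_genes, batch)
    truth = GroundTruth(genes=truth_genes, strains=truth_strains)
    return SimulatedCohort(
        annotation=annotation, karyotypes=karyotypes, mrna=mrna, protein=protein,
        truth=truth, spec=spec,
    )


def _strain_truth(karyotypes, truth_genes, batch) -> pd.DataFrame:
    rows = []
    for k in karyotypes:
        aneu = k.aneuploid_chromosomes
        classes = {round(np.log2(k.chrom_cn[c] / k.ploidy), 9) for c in aneu}
        atten = np.nan
        if len(classes) == 1:
            # per-strain true attenuation: 1 - median slope of cis genes
            slopes = truth_genes.loc[
                truth_genes["chromosome"].isin(aneu), "protein_slope"
            ]
            atten = 100.0 * (1.0 - float(slopes.median()))
        rows.append(
            {
                "strain_id": k.strain_id,
                "ploidy": k.ploidy,
                "aneuploid": not k.is_euploid,
                "aneuploid_chromosomes": ";".join(aneu),
                "true_attenuation_pct": atten if aneu else np.nan,
                "batch": batch[k.strain_id],
            }
        )
    return pd.DataFrame(rows).set_index("strain_id")


def simulate_silac(rates, times=(90.0, 135.0, 180.0), noise_cv: float = 0.0,
                   model: str = "loglinear", seed: int = 0) -> pd.DataFrame:
    """Simulate a long-format dynamic-SILAC H/L table.

    ``rates`` maps (strain_id, protein_id) -> degradation rate k in 1/min
    (a dict, or a protein x strain DataFrame).  Under the ``loglinear``
    model H/L = exp(k t) (1 + d); under the first-order ``kinetic`` model
    H/L = (exp(k t) - 1)(1 + d), with d ~ N(0, noise_cv).
    """
    if model not in ("loglinear", "kinetic"):
        raise ValidationError(f"unknown SILAC model {model!r}")
    if isinstance(rates, pd.DataFrame):
        pairs = [
            (s, p, rates.at[p, s])
            for p in rates.index for s in rates.columns
            if np.isfinite(rates.at[p, s])
        ]
    else:
        pairs = [(s, p, k) for (s, p), k in rates.items()]
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValidationError("SILAC time points must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for strain, protein, k in pairs:
        if k <= 0:
            raise ValidationError(f"rate must be positive for ({strain}, {protein})")
        base = np.exp(k * times)
        if model == "kinetic":
            base = base - 1.0
        noise = 1.0 + rng.normal(0, noise_cv, times.size) if noise_cv else 1.0
        ratios = base * noise
        for t, r in zip(times, np.atleast_1d(ratios)):
            rows.append(
                {"strain_id": strain, "protein_id": protein,
                 "time_min": float(t), "hl_ratio": float(r)}
            )
    return pd.DataFrame(rows)


def simulate_precursors(protein_matrix: ExpressionMatrix | pd.DataFrame,
                        precursors_per_protein: int = 3,
                        n_qc_samples: int = 3,
                        n_batches: int = 1,
                        batch_shift_log2: float = 0.0,
                        noise_cv: float = 0.0,
                        seed: int = 0) -> tuple[ExpressionMatrix, pd.Series]:
    """Expand a complete protein matrix into a precursor x sample matrix.

    Each precursor is its parent protein's abundance times a fixed
    per-precursor efficiency times multiplicative noise.  QC samples are
    replicates of a pooled sample (the per-protein mean across samples).
    Batch shifts multiply whole sample columns on the linear scale.

    Returns the precursor matrix (with batch / QC metadata) and the
    precursor -> protein map.
    """
    if precursors_per_protein < 1:
        raise ValidationError("precursors_per_protein must be >= 1")
    values = (
        protein_matrix.values
        if isinstance(protein_matrix, ExpressionMatrix)
        else protein_matrix
    )
    if values.isna().any().any():
        raise ValidationError("precursor simulation requires a complete protein matrix")
    rng = np.random.default_rng(seed)
    proteins = list(values.index)
    samples = list(values.columns)
    qc_names = [f"QC{i + 1}" for i in range(n_qc_samples)]
    pooled = values.mean(axis=1)

    prec_ids, parents, eff = [], [], []
    for p in proteins:
        for j in range(precursors_per_protein):
            prec_ids.append(f"{p}_pr{j + 1}")
            parents.append(p)
            eff.append(2.0 ** rng.normal(-1.0, 0.5))
    eff = np.array(eff)

    base = values.to_numpy()[
        np.repeat(np.arange(len(proteins)), precursors_per_protein), :
    ]
    pooled_base = pooled.to_numpy()[
        np.repeat(np.arange(len(proteins)), precursors_per_protein)
    ]
    full = np.concatenate(
        [base, np.tile(pooled_base[:, None], (1, n_qc_samples))], axis=1
    )
    full = full * eff[:, None]
    if noise_cv:
        full = full * (1.0 + rng.normal(0, noise_cv, full.shape))
    all_samples = samples + qc_names
    batches = pd.Series(
        [f"B{(i % n_batches) + 1}" for i in range(len(samples))]
        + ["B1"] * n_qc_samples,
        index=all_samples, name="batch",
    )
    if n_batches > 1 and batch_shift_log2:
        # deterministic alternating shifts: batch b gets b * batch_shift_log2
        shift = np.array(
            [batch_shift_log2 * (int(b[1:]) - 1) for b in batches]
        )
        full = full * 2.0 ** shift[None, :]
    meta = pd.DataFrame(
        {"batch": batches, "is_qc": [s in qc_names for s in all_samples]}
    )
    matrix = ExpressionMatrix(
        "precursor",
        pd.DataFrame(full, index=pd.Index(prec_ids, name="precursor_id"),
                     columns=all_samples),
        strain_meta=meta,
    )
    prec_map = pd.Series(parents, index=prec_ids, name="protein_id")
    return matrix, prec_map
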