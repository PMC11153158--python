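# dosagecomp

Dosage-compensation analysis for aneuploid yeast cohorts.

Natural *Saccharomyces cerevisiae* isolates carry whole-chromosome
aneuploidies surprisingly often, and — unlike lab-engineered aneuploids —
buffer most of the surplus gene dosage at the protein level.  `dosagecomp`
implements the quantitative machinery for studying this phenomenon in a
cohort of strains profiled on several omics layers: it integrates per-strain
karyotypes with transcriptome and proteome matrices, quantifies attenuation
gene-by-gene and strain-by-strain, characterizes the *trans* response on
euploid chromosomes, and estimates protein turnover from dynamic-SILAC
time courses.  A synthetic-cohort generator with full ground truth makes
every stage testable at desk scale.

It is aimed at computational biologists working with multi-omics panels of
natural isolates (or any collection of strains with known karyotypes) who
need reproducible, statistically explicit attenuation calls.

## The model

For gene *g* on chromosome *c* in strain *s*, the relative dosage change is

    Δ_cs = log2(CN_cs / ploidy_s)

and relative expression is the log2 ratio of the strain's abundance to the
median abundance of the same gene across all euploid strains, normalized so
that each strain's median over euploid-chromosome genes is 0.  Two
complementary statistics quantify dosage compensation:

* **Gene-level attenuation slope** — the OLS coefficient *b* of relative
  expression on Δ across strains (gains only, ≥ 3 aneuploid observations).
  *b* = 1 means expression follows dosage (*y* = *x*); *b* = 0 means full
  compensation; attenuation % = 100 (1 − *b*).  A gene is called attenuated
  when *b* < 0.85.
* **Strain-level attenuation** — per (strain, CN-change class), a two-sided
  one-sample Wilcoxon signed-rank test of the class's ratios against Δ,
  with the Hodges–Lehmann pseudomedian *m* (median of Walsh averages)
  giving attenuation % = 100 (1 − *m*/Δ).  Strains with |*m*| < 0.1 at the
  protein level are flagged as reverted to euploidy.

Quality control mirrors a DIA proteomics post-search pipeline (sample
z-score outliers, 80 % precursor presence, QC CV < 0.3, per-batch median
centering, median protein summarization, KNN imputation), and karyotype
errors are caught by a ±4 SD consistency filter between relative chromosome
copy number and median chromosomal mRNA ratios.

Turnover rates k_dp come from least squares on log-transformed heavy/light
SILAC ratios over the labelling time course (half-life = ln 2 / k_dp), with
both a literal ln(H/L) fit and a first-order kinetic ln(1 + H/L)
through-origin fit available.

## Worked example

```python
from dosagecomp.simulate import CohortSpec, simulate_cohort
from dosagecomp.integrate import build_integrated_cohort
from dosagecomp.genes import fit_gene_slopes, rolling_threshold, compare_layers
from dosagecomp.strains import strain_wilcoxon, detect_reverted

cohort = simulate_cohort(CohortSpec(seed=42))          # 200 strains, 16 chromosomes
ic = build_integrated_cohort(
    {"mRNA": cohort.mrna, "protein": cohort.protein},
    cohort.karyotypes, cohort.annotation,
)
tests = strain_wilcoxon(ic.layers["protein"], ic.karyotypes, cohort.annotation)
detect_reverted(tests, ic.karyotypes)
prot = fit_gene_slopes(ic.layers["protein"], ic.cn, ic.karyotypes, cohort.annotation)
mrna = fit_gene_slopes(ic.layers["mRNA"], ic.cn, ic.karyotypes, cohort.annotation)
```

prints (via the summaries shown in `tests/` and the CLI logs):

```
strains kept: 199  genes with slopes: 188
fraction of proteins attenuated at slope < 0.85: 0.702
median slope mRNA 1.00 vs protein 0.62 (Spearman rho 0.03)
strain S0017: CN class 1.000, pseudomedian 0.610, attenuation 39.0% (BH p 4.73e-14)
```

One strain of the 200 was excluded by the CN–mRNA mismatch filter; of the
genes measurable on aneuploid chromosomes, 70 % of proteins are attenuated
at the 0.85 threshold while mRNA tracks dosage ~1:1 — the protein-specific
buffering the statistics are designed to expose.  Strain S0017 is a haploid
with a duplicated chromosome (Δ = 1) whose proteome sits at a pseudomedian
of 0.61, i.e. 39 % of the extra dosage is removed.

The same pipeline runs from the shell on TSV inputs:

```sh
dosagecomp --out-dir out --seed 42 run            # synthetic end-to-end run
dosagecomp --out-dir out run --mrna mrna.tsv --protein protein.tsv \
    --karyotypes karyotypes.tsv --annotation annotation.tsv
```

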