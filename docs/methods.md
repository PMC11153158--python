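# Methods

## Relative dosage and expression

A strain's karyotype is its basal ploidy (1–5) plus an integer copy number
per chromosome.  The relative copy-number change of chromosome *c* in
strain *s* is Δ_cs = log2(CN_cs / ploidy_s): 0 on euploid chromosomes,
+0.585 for a trisomic diploid chromosome, +1 for a disomic haploid one.

Relative expression is computed gene-wise as the log2 ratio of a strain's
abundance to the median abundance of the same gene across euploid strains
(`all_euploid`), or across euploid strains of the same ploidy
(`ploidy_wise`).  Reference medians use present values only and require at
least three euploid observations per gene — the threshold is a
conservative package choice; with fewer, the gene's relative row is left
missing rather than anchored to an unstable reference.  Ratios are then
trans-normalized strain by strain: the median log2 ratio over genes on
that strain's euploid chromosomes is subtracted from the whole column, so
global shifts (growth state, loading) cannot masquerade as dosage effects.
The normalization is idempotent and leaves the per-strain
euploid-chromosome median exactly 0.

Karyotype/transcriptome inconsistencies are detected by pooling, over all
(strain, chromosome) pairs, d = Δ − median chromosomal mRNA ratio, and
flagging any strain with a pair deviating more than 4 sample standard
deviations from the pooled mean.  Exclusion triggers a full second pass so
the euploid reference is not biased by the excluded strains; the two-pass
flow is explicit in the driver rather than hidden inside the operation.
When the pooled sd is below 1e-9 log2 units the filter is degenerate and
flags nothing (any flag would be floating-point noise).  Whether gains and
losses should pool separately is unknowable from the description we
follow; they are pooled.

## Gene-level attenuation

Per gene, ordinary least squares of relative expression on Δ over all
non-reverted strains with Δ ≥ 0 (euploid points anchor the baseline;
chromosome losses are excluded by default because loss and gain responses
need not mirror each other, and can be included via a flag for
exploration).  Natural-cohort fits include an intercept and require at
least three aneuploid observations; disome-collection fits have exactly
one aneuploid point per gene and are forced through the origin, where the
slope reduces to the disome's log2 ratio.  The asymmetry is intentional:
an intercept is not identifiable from a single aneuploid point.
Attenuation % = 100 (1 − slope); the attenuated call uses the 0.85 slope
threshold.  The rolling-threshold analysis reports, per threshold, the
fraction of genes below it and the median slope among them.

Property associations (complex membership, interaction counts, and any
user-supplied covariate) compare attenuated versus non-attenuated genes
with two-sample two-sided Mann–Whitney tests, reported raw and
BH-adjusted within the property family, plus the rank AUC = U/(n₁n₂).
Spearman correlations between layers use the asymptotic p-value; an exact
permutation p is available for n ≤ 8 and exists for oracle testing, since
real cohorts are far above that size.

## Strain-level attenuation

Per (strain, CN-change class): a two-sided one-sample Wilcoxon signed-rank
test of the class's gene ratios against the expected median Δ, with at
least 5 genes.  Zero differences are dropped and tied absolute differences
receive mid-ranks; the exact null is used for n ≤ 25 without ties, the
continuity-corrected normal approximation otherwise.  BH adjustment spans
all (strain × class) tests of one omics layer.  The accompanying
Hodges–Lehmann pseudomedian (median of all Walsh averages, computed by the
O(n²) definition — n here is at most a few hundred genes) yields
attenuation % = 100 (1 − pseudomedian/Δ), reported only for strains whose
aneuploid chromosomes share a single Δ (otherwise a single percentage is
not meaningful).  Aneuploid strains whose protein-level pseudomedians all
lie strictly inside (−0.1, 0.1) are marked reverted to euploidy and
excluded from gene-level regressions; the exact endpoints count as not
reverted (open interval — a deliberate tie-break).

Pooled per-class distribution summaries flag classes with fewer than 300
(gains) or 50 (losses) data points as excluded from visualization.  The
chromosome-wide dosage-response line is OLS of per-class median expression
on Δ over gain classes; slope 1 − a corresponds to an average attenuation
of 100 a %.  The aneuploid protein load sums copies/cell of genes on
aneuploid chromosomes weighted by |CN/ploidy − 1| (surplus form); a
CN/ploidy-weighted variant is provided behind a flag without endorsement,
since "ploidy-adjusted" admits both readings.

## Trans response

Trans expression is defined on euploid chromosomes of aneuploid strains;
cis entries are masked before any statistic.  Per-gene medians feed
ranked-list enrichment tools; per-gene one-sample t-tests against μ = 0
(classical t, df = n − 1, n ≥ 3, nonzero variance) with layer-wide BH
give the volcano.  Note the μ = 0 null is only approximate: the euploid
reference median carries sampling noise of order σ·√(π/2)/√n_euploid per
gene, which slightly inflates raw t-statistics in small cohorts; the
package's FDR check (20 null cohorts) measures the realized BH-significant
fraction under the default cohort size.  Signature gene sets (ESR, CAGE,
APS, proteasome components) are consumed as labels in the annotation
table, never bundled.

## Proteomics preprocessing

Sample outliers: |z| > 2.5 on the column total signal or on the present
precursor count, z against the cohort mean and sample sd (ddof = 1).
Precursor filter: present in ≥ 80 % of strain samples and linear-scale
CV < 0.3 across QC samples; precursors with fewer than two present QC
values cannot demonstrate precision and are dropped with the CV failures.
Batch correction multiplies each batch by one factor bringing its median
precursor intensity to the global pre-correction median — additive in
log2, rank-preserving within batches.  Proteins are summarized as the
median of present precursors (a deliberately simple, auditable stand-in
for inference-based quantifiers; a `summarizer` hook accepts an external
one).  KNN imputation (default k = 10) fills missing cells from the k
nearest rows by Euclidean distance on mutually present log2 values,
rescaled by shared-column count (the NaN-aware Euclidean kernel), with a
row-mean fallback when no neighbouring row has the column; present values
are never altered.  Orientation (rows-as-genes), k, and metric are
package choices — the upstream description names only "KNN imputation".

## Turnover

Rates are fitted per (strain, protein) series with ≥ 2 positive-ratio
time points.  The default `literal` transform regresses ln(H/L) on time
with an intercept — the direct reading of "log-transformed H/L ratios";
the `kinetic` transform regresses ln(1 + H/L) through the origin, which
exactly inverts first-order label incorporation H/L = e^{kt} − 1.  Both
are reported in output headers because the upstream description does not
disambiguate them; applying the literal fit to kinetic-model data biases
k upward (d/dt ln(e^{kt} − 1) = k·e^{kt}/(e^{kt} − 1) > k), most strongly
at early times — asserted directionally in the tests.  Natural log is used
throughout the kinetics; half-life = ln 2 / k_dp, so half-life · k_dp is
ln 2 identically.  No doubling-time correction is applied by default (most
proteins are stable on the 3 h window); a `doubling_time_min` hook
subtracts the dilution rate when wanted.  Matrices are filtered to
proteins with rates in ≥ 80 % of strains, KNN-imputed on the raw-rate
scale, then quantile-normalized across strains (rank-wise order-statistic
means, ties averaged) — filter → impute → normalize, in that order.
Context comparisons (aneuploid chromosome / euploid chromosome of
aneuploid strain / euploid chromosome of euploid strain) require ≥ 3
observations per context.  The deletion-collection contrast calls a
chromosome duplicated at median log2 fold change > 0.8, averages fold
changes of its proteins across duplicated strains, and applies a Welch
two-sided t-test between the < Q1 and > Q3 reference-half-life groups
(Welch, because nothing guarantees equal variances).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_strains / chromosomes / genes | 200 / 16 / 94 per chromosome | desk-scale cohort with the yeast chromosome count |
| ploidy weights | 1n 0.25, 2n 0.60, 3n 0.08, 4n 0.04, 5n 0.03 | mostly diploid natural cohort, haploids next, rare high ploidies |
| aneuploidy rate | 0.15 | ~15 % aneuploid strains |
| gain fraction | 0.884 | gains dominate losses 88.4 %/11.6 % |
| complex-aneuploidy rate | 0.27 | ~27 % of aneuploids carry a second aneuploid chromosome |
| mRNA slope | N(1.0, 0.05) | transcript dosage ~1:1 with copy number |
| protein slope mixture | 0.704·N(0.50, 0.15) + 0.296·N(1.00, 0.05) | ~70 % of genes truly below the 0.85 threshold; complex members biased +0.2 to the attenuated component, with the non-complex probability compensated so the marginal stays at 0.704 |
| noise | 0.2 log2 sd per layer | between replicate-level and cohort-level variability of a DIA pipeline |
| trans proteasome shift | +0.3 log2, protein layer, aneuploids only | the induction is real but unquantified upstream; a free parameter with a moderate default |
| missingness | 4 % | matches a well-filtered DIA panel |

Gains are modelled as CN = ploidy + 1 and losses as ploidy − 1 (single-
chromosome events dominate; arbitrary karyotypes can be supplied
explicitly).  mRNA and protein noise are independent — no mRNA→protein
error propagation — which keeps slope recovery analytically checkable.
Baselines are log-normal; batch shifts multiply on the linear scale; SILAC
tables follow either H/L = e^{kt}(1 + δ) or (e^{kt} − 1)(1 + δ) with
δ ~ N(0, cv).  Identical spec (including seed) yields byte-identical
output.

What the generator does *not* emulate: linkage between genes on a
chromosome beyond the shared Δ, growth-rate or condition dependence,
peptide-level structure (precursors are independent multiplicative
perturbations of their parent protein), segmental aneuploidy, and
mRNA-correlated protein noise.  Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
every failure mode of real cohorts.

## Validation sizes and numerical notes

The test suite validates parameter recovery at deliberately modest sizes
chosen for fast, deterministic runs: the default 200-strain cohort for
gene-slope recovery and threshold fidelity (10 seeds); 40-strain trisomic-
diploid cohorts with 60 genes/chromosome for strain-level attenuation at
planted 14 %/25 %/58 % compensation, with the ±2-point check applied to
the cohort mean over ~30 trisomic strains (a single strain's pseudomedian
at σ = 0.2 carries ~4.5 points of sampling noise, so per-strain equality
is asserted only at σ = 0); 400-series SILAC runs (the desk-scale analogue
of the ~1,100 proteins a labelling run quantifies per isolate) over 5
seeds for turnover recovery; and 20 null cohorts for FDR control.

A note on gene-slope precision: the OLS slope sampling sd is
σ/√Σ(Δ − Δ̄)², so with ~3–6 aneuploid observations per qualifying gene at
Δ ≤ 1 and σ = 0.2, per-gene estimates carry ~0.10–0.25 of irreducible
noise; the per-gene RMSE the acceptance script reports reflects this
leverage-limited bound, while the estimates are unbiased (mean bias ≈ 0)
and exact to numerical precision at σ = 0.  Tightening per-gene RMSE
requires more aneuploid observations per chromosome, not algorithmic
changes.

Other numerical conventions: all expression logs are base 2; missing
values are explicit NaN, never sentinels; medians of even-count reference
sets are midpoint means, so the per-gene euploid median ratio is exactly 0
only for odd reference counts (the even-count gap is the arithmetic-vs-
geometric mean difference, ~1e-4 at σ = 0.2); BH adjustment follows the
standard step-up procedure and is cross-checked against the definitional
brute force; degenerate cases (zero-variance covariates, all-missing rows,
fewer samples than a sd needs) raise validation errors naming the
offender.

## Known limitations

* The mismatch filter's 4 SD rule is calibrated by the pooled empirical
  distribution; in very clean cohorts a single pair can exceed 4 SD by
  chance (~normal tail × number of pairs), so occasional false exclusions
  are expected and are reported with reasons rather than silently dropped.
* maxLFQ-style protein inference is intentionally out of scope; the median
  summarizer is transparent but discards peptide-level covariance.
* The turnover transforms bracket, but cannot resolve, the upstream
  ambiguity between ln(H/L) and ln(1 + H/L); cross-fit bias is documented
  and tested directionally.
* Identifier consistency (strain names, systematic ORF ids) across input
  tables is the caller's responsibility; no registry is bundled.
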