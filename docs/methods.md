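# Methods

`regulink` implements the statistical core of a germline–somatic regulatory
integration analysis: linking inherited risk variants (GWAS SNPs) to
transcription-factor biology and somatic context (a gene-fusion status), and
carrying the result through to gene signatures and survival. This note
records the models, the defaults and why they were chosen, and what the
synthetic cohorts do and do not establish.

## Models and procedures

**Genotype QC.** SNPs are filtered on call rate (≥ 90%), minor allele
frequency (≥ 0.01) and Hardy–Weinberg equilibrium (1-df chi-squared on
observed genotype counts against expectations from the observed allele
frequency; SNPs with p < 0.05 removed). The chi-squared form is used rather
than the exact test because only a generic "HWE test" is conventional at
these sample sizes; monomorphic SNPs trivially satisfy HWE and are instead
removed by the MAF filter.

**cis-eQTL model.** For a SNP–gene pair, expression (log scale) is regressed
on the additive 0/1/2 genotype with an intercept: `e = a + b·g + ε`. The test
is the two-sided t test on `b` with n−2 df — the linear model of standard
matrix-eQTL practice. No covariates enter the base model; a pair is declared
*cis* when |variant position − TSS| ≤ 1 Mb (inclusive). Stratified analysis
re-fits the identical pair set within each clinical stratum (fusion-positive
/ fusion-negative) and pooled; strata with < 3 complete pairs or constant
genotype are flagged untestable rather than dropped silently. Missing
genotypes are removed pairwise. Benjamini–Hochberg q-values are reported per
stratum alongside nominal p; no p filtering is hard-coded.

**Co-expression.** Pearson and Spearman coefficients against a query gene,
genome-wide, ranked by Pearson r descending; p-values by the t transform with
n−2 df (adequate for the n ≥ 30 cohorts this targets). Zero-variance genes
are excluded and logged; ties in the top-k panel boundary break by
lexicographic gene id so panels are reproducible.

**Interval algebra.** BED semantics throughout (0-based half-open); variant
positions are 1-based and converted at the membership test. Merging
coalesces touching intervals, matching peak-union practice. The three-way
partition of two normalized peak sets (unique-A / common / unique-B) is exact
at base-pair level: the outputs are pairwise disjoint and conserve the union
span, which tests verify against a per-base boolean oracle. Peak-level
co-occupancy counts a peak of A as co-occupied if it shares ≥ 1 bp with any B
peak — the familiar "m of n binding sites co-occupied" quantity of ChIP-seq
comparisons — and is deliberately asymmetric in its arguments.

**Peak-to-gene annotation** assigns each peak to the gene whose TSS is
nearest the peak midpoint, within a configurable window (default 100 kb).
Equidistant ties go to the lower TSS coordinate, then lexicographic gene id.
External annotators make similar but unstated choices; here the rule is
explicit and tested.

**Motif allele scoring.** A PWM is scored as the sum over columns of
log2((p + 1e−3)/background); the pseudocount keeps zero entries finite. All
windows covering the SNP on both strands are scored for the reference and the
alternate allele; the report is (best ref, best alt, delta). This is a
simplified allele-delta score, not a calibrated affinity test: it flags
direction and magnitude of motif disruption, nothing more.

**SNP enrichment in binding-site partitions.** SNP counts across the three
disjoint partitions are tested by chi-squared against span-proportional
expectation (df = partitions − 1), with per-partition fold
(observed share)/(span share). SNPs outside every partition are excluded —
a conditional-on-binding analysis — but counted and reported. Because
span-proportionality ignores SNP density heterogeneity, an optional
permutation null (uniform re-placement over the pooled spans) is provided
and labelled in the output. The LD expansion keeping proxies at r² ≥ 0.8 is
inclusive at the boundary; the threshold is an argument.

**Signatures.** A sample's score is the weighted sum over panel genes of the
gene's z-score across the cohort (sd with n−1). Weights default to 1 — the
plain "z-score sum" — because no published weighting accompanies these
panels; a weight column is accepted. Scores are therefore invariant to any
per-gene affine rescaling of expression, which is tested as an identity. The
CCP-style score is the mean (not sum) z-score of a caller-supplied cell-cycle
panel, so its scale does not grow with panel size.

**Survival.** Kaplan–Meier curves and log-rank tests come from lifelines.
The Cox proportional-hazards model is fitted in-package by Newton–Raphson on
the partial likelihood, because the acceptance requirement of 1e−6 agreement
with a grid-search oracle exceeds the convergence tolerance available from
the off-the-shelf fitter, and because Breslow tie handling was wanted as the
default (Efron is available via `ties="efron"`; the two coincide on tie-free
data, and both are cross-checked against lifelines in the tests). Covariates
are centered before fitting for numerical stability; steps are halved
whenever the linear predictor would exceed ±500, and |lnHR| > 20 triggers a
separation warning. Wald inference from the observed information; 95% CI as
lnHR ± 1.96·se. Median stratification sends scores equal to the median to
the "high" group (the rule must land somewhere; it is documented and the
group sizes are reported).

**Meta-analysis.** Fixed-effect inverse-variance pooling of per-study lnHR:
weights 1/se², pooled se = 1/√Σw, Cochran Q and I² = max(0, (Q−df)/Q)·100.
Fixed-effect pooling is conventionally reserved for I² < 30%, so larger
values emit a warning rather than switching models silently.

**Assay formulas.** qPCR standard curves are least-squares lines of Ct on
log10 input. The 3C value is 10^((Ct − intercept)/slope), normalized to the
loading-control amplicon's value computed the same way; replicate averaging
happens after normalization. ΔΔCt fold changes use efficiency 2 exactly
(2^−ΔΔCt), with replicate Cts averaged on the Ct scale (a flag is not
offered for linear-scale averaging because the Ct scale is the standard);
the standard-curve efficiency 10^(−1/slope) is available in reports for
primer diagnostics. Dual-luciferase activity is the per-well firefly/renilla
ratio, averaged per construct and expressed relative to the baseline
construct; wells with nonpositive renilla are excluded and logged.

## The synthetic cohort generator

The generator produces cohorts carrying exactly the structure the analyses
assume, so every stage is testable end-to-end without external downloads.

- **Genotypes.** One MAF per LD block, drawn uniformly from `maf_range`
  (default 0.1–0.4). Haplotype alleles follow a Markov copy along the block:
  each SNP copies its left neighbour with probability √r² and otherwise
  redraws from the block MAF. This yields adjacent-SNP genotype correlation
  √r² (hence squared correlation `within_block_r2`) while preserving the
  marginal MAF, with no external haplotype panel. Blocks are independent.
- **Expression.** The target gene is `1 + β·g·f + N(0, σ²)` where `f` is the
  fusion indicator (dropped when `fusion_dependent` is off), β = `eqtl_beta`
  (default 1 expression unit per allele) and σ = `noise_sd` (default 1).
  Fusion status is Bernoulli(`fusion_fraction`, default 0.4 — roughly the
  fusion-positive share of stratified tumour cohorts). A regulator gene is
  constructed to correlate with the target at `coexpr_rho` (default 0.8)
  among fusion-positive samples and is independent noise elsewhere;
  background genes are standard normal.
- **Peak landscape.** One synthetic chromosome ("chrS", default 10 Mb);
  default 500 peaks of 200 bp per factor. A fraction `cooccupancy_target`
  (default 0.7, the co-occupancy scale reported for these factors) of A
  peaks receives a B peak nested in their central half, so the realized
  peak-level co-occupancy is exact; remaining B peaks land in the background
  without touching other peaks. GWAS SNPs (default 1000; 60% inside binding
  partitions) are placed so that the span-normalized share of the common
  partition equals `snp_enrichment_fold` in expectation — i.e. the planted
  fold is defined on the same scale the enrichment test measures. With
  fold = 1 placement reduces to a span-proportional multinomial, making the
  chi-squared null calibration exact by construction.
- **Survival.** Exponential event times with hazard
  λ0·exp(`surv_lnHR`·z-score), λ0 set for a 60-month baseline median (a
  plausible advanced-cancer scale; months throughout). Censoring is
  independent Uniform(0, T_max) with T_max solved by root-finding so the
  expected censoring fraction equals `censor_rate` (default 0.2).

What the generator does **not** emulate: realistic recombination maps or
population structure; expression covariance beyond the one planted
regulator; confounding between genotype and fusion status; informative
censoring; sequence-level fusion breakpoints. Passing tests therefore show
that the estimators are correct and calibrated under their assumed models —
not that those models capture every feature of real tumour cohorts.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks use 1000 random instances each; calibration uses
2000 replicates per null (cohorts of 60 samples for eQTL, 100-peak
landscapes with 200 SNPs for enrichment, 100 subjects for Cox), giving a
Monte-Carlo band of 0.05 ± 3·√(0.05·0.95/2000) ≈ ±0.015 on the type-I rate.
Parameter recovery uses 100 cohorts of 1000 samples (≈500 per stratum) for
the stratified-eQTL power, one 500-peak landscape with 1000 SNPs for fold
recovery, and 200 cohorts of 500 subjects for the Cox bias. These sizes were
chosen so each property is measured at the precision its acceptance band
requires.

## Known limitations

- The eQTL model is two-variable OLS; covariate adjustment is accepted but
  no PEER/factor estimation is provided.
- Correlation p-values use the t approximation, which is anti-conservative
  below n ≈ 10.
- The permutation null for partition enrichment re-places SNPs uniformly
  within the pooled partition spans; it does not model LD clumping of the
  SNP set itself.
- `cooccupancy_target` can make extreme `snp_enrichment_fold` values
  geometrically infeasible (the common span bounds the achievable fold); the
  generator raises rather than silently truncating.
- The case–control association is allelic (2×2 chi-squared with Haldane
  correction), not genotypic or covariate-adjusted logistic regression.
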