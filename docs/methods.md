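# Methods

## Scope and model

`smrpipe` implements a two-stage analysis of GWAS and eQTL summary
statistics:

1. **Fixed-effects inverse-variance meta-analysis.** For a SNP with
   per-cohort effect estimates β_i and standard errors SE_i, each cohort
   receives weight w_i = 1/SE_i². The combined effect is
   β = Σβ_i w_i / Σw_i with SE = sqrt(1/Σw_i), Z = β/SE, and a two-sided
   standard-normal p-value. No heterogeneity statistic is computed: the
   model is strictly fixed-effects, which assumes every cohort estimates
   the same underlying per-allele effect and differs only by sampling
   noise.

2. **Summary-data Mendelian randomization (SMR).** With a SNP z as
   instrument, gene expression x as exposure and the trait y as outcome,
   the causal effect of expression on trait is the Wald ratio
   b_xy = b_zy / b_zx. The SNP→expression effect is recovered from the
   eQTL Z-score on the standardized scale,

       se_zx = 1 / sqrt(2 f (1 − f) (n + z²)),   b_zx = z · se_zx,

   where f is the effect-allele frequency and n the eQTL sample size. The
   sampling variance of the ratio is the first-order Delta expansion with
   zero cross-covariance (GWAS and eQTL samples are independent), and
   T_SMR = b_xy²/var(b_xy) is referred to χ² with 1 df. Because only the
   Z-scores have a known distribution, the operative statistic is the
   Z-form

       T_SMR = Z_zy² Z_zx² / (Z_zy² + Z_zx²),

   which is algebraically identical to the Delta form whenever both SEs
   are derived from the same Z-scores; the Delta form is retained as an
   internal consistency check (`statistic="delta"`). A diagnostic variance
   in terms of phenotype variances and R² values (`variance_from_r2`) is
   exposed but never used by the pipeline, since it needs individual-level
   variance components that summary data do not provide.

The method's assumptions are the usual instrumental-variable ones: the
instrument affects the trait only through the gene's expression (no
horizontal pleiotropy), instruments are valid (nonzero b_zx), and the two
summary datasets come from non-overlapping samples of the same population.
No heterogeneity (HEIDI-type) test is included, so linkage or pleiotropy
that violates these assumptions is not detected — results are
associations under the stated model, not proofs of causality.

## Testing policy

Instrument selection takes every (gene, SNP) pair whose eQTL p-value is at
most `instrument_p_threshold` (default 5×10⁻⁸, the conventional
genome-wide level). The default `per_pair` mode tests each qualifying pair
separately, which is what produces many-SNPs-per-gene output; a
`top_per_gene` mode restricts to each gene's smallest-p eQTL (ties broken
by larger |Z|, then SNP id). Multiple testing is controlled by Bonferroni
at family-wise rate α (default 0.05) with denominator m equal to the
number of SMR tests actually performed.

T_SMR ≤ min(Z_zy², Z_zx²) always holds for the Z-form, so with finite
instrument strength the test is slightly conservative: at mean |Z_zx| ≈ 10
the null rejection rate at α = 0.05 is ≈ 0.046 rather than 0.050. This is
a property of the statistic, not a defect of the implementation.

## Allele harmonization

The inputs never guarantee a shared effect-allele orientation. Within the
meta-analysis, each SNP is re-oriented to a canonical orientation — the
alphabetically first allele of the pair carries the effect — so results
are exactly invariant to cohort order; records entering on the opposite
orientation get β negated and frequency complemented. SNPs whose allele
pairs disagree across cohorts are excluded with a logged reason, and
strand-ambiguous pairs (A/T, C/G) are dropped by default because their
orientation cannot be resolved from summary data. The same re-orientation
is applied to eQTL records against the GWAS effect allele before the Wald
ratio (Z sign flipped on swapped alleles). Eq-level statistics are
invariant to a joint allele flip, so the canonical choice affects signs of
b_zx/b_zy only, never T_SMR, p, or b_xy.

The combined effect-allele frequency is the N-weighted mean of cohort
frequencies; it feeds the standardized-effect formula for se_zx.

## MAF filter

GWAS records with minor-allele frequency min(eaf, 1−eaf) ≤ 0.001 are
removed before meta-analysis (threshold configurable). Placement before
harmonization is a pipeline choice; exclusion counts appear in the run
log, and record conservation (input = output + exclusions) holds at every
stage.

## Synthetic data

The generator emulates the minimal structure the estimators assume, i.e.
the structural chain the Wald ratio identifies:

* genotype dosages are two Bernoulli(maf) draws per SNP (Hardy–Weinberg,
  linkage equilibrium);
* expression x_g = Σ_j b_zx(j,g)·z_j + ε_x and trait y = Σ_g b_xy(g)·x_g +
  ε_y, with noise scaled so both phenotypes have unit variance in
  expectation (so per-allele effects and the standardized Z-score formula
  agree exactly);
* each SNP instruments exactly one gene.

Two paths produce summary statistics. The individual-level path simulates
cohorts and summarizes each SNP by OLS (slope, SE from residual variance,
t-test with n−2 df); it is the slow oracle. The summary-level path draws
statistics directly from their sampling laws — eQTL
Z ~ N(b_zx·sqrt(2f(1−f)·n_eqtl), 1) and GWAS β ~ N(b_zx·b_xy, SE²) with
SE = 1/sqrt(2f(1−f)·n_cohort) — and is used for calibration, recovery and
power studies at thousands of replicates. A test verifies the two paths
agree (per-SNP SE within 10% at n = 5,000).

What the generator does **not** emulate: linkage disequilibrium, minor
allele frequency spectra skewed toward rare variants, population
structure, sample overlap between GWAS and eQTL, horizontal pleiotropy,
case-control ascertainment, or winner's-curse-inducing discovery
filtering beyond the instrument p-threshold. Passing tests therefore show
the estimators are correct under their own assumptions, not that those
assumptions hold in any real cohort.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_per_cohort | (394,929, 32,965) | the two-cohort UK-scale GWAS design the pipeline targets |
| n_eqtl | 5,311 | blood-eQTL scale |
| n_genes × snps_per_gene | 50 × 20 | desk-scale panel large enough for aggregation/network output |
| frac_causal_genes | 0.06 (3 of 50) | sparse causal architecture |
| b_xy_causal | 0.2 trait-SD per expression-SD | moderate, detectable effect |
| b_zx_range | (0.1, 0.5) expression-SD per allele, random sign | realistic cis-eQTL effect range: top cis-eQTLs explain ~1–25% of expression variance at common frequencies |
| maf_range | (0.05, 0.5) | common variants, consistent with instruments needing decent power |
| seed | 42 | fixture identity |

One global seed drives everything; per-cohort streams and the eQTL stream
are spawned deterministically from (seed, stream-index), so fixtures are
byte-reproducible and cohorts are mutually independent.

## Numerical choices

* p-values of exactly 0 in input files are clamped to the smallest
  positive float with a logged warning (underflow is common in large-N
  scans); computed normal/χ² tail probabilities are floored the same way.
* The Delta variance is evaluated in its expanded form
  se_zy²/b_zx² + b_zy²·se_zx²/b_zx⁴ − 2·b_zy·cov/b_zx³, which is defined
  at b_zy = 0; tests verify agreement with the factored ratio form to
  1e-12.
* T_SMR at Z_zy = Z_zx = 0 is 0 by convention (p = 1), logged.
* Result tables are written at 12 significant digits, making the
  write/read round trip lossless to ~1e-10 relative error and re-runs
  byte-identical.
* Instrument ties in `top_per_gene` break by p, then |Z| descending, then
  lexicographic SNP id, so selection is deterministic.

## Problem sizes used by the test suite and acceptance script

Calibration uses 20,000 null replicates; parameter recovery uses 2,000
single-SNP genes at n_gwas = 100,000 and n_eqtl = 5,000; the end-to-end
fixture is the default 50-gene configuration. These sizes give Monte-Carlo
standard errors of ~0.0015 on the calibration rate and ~0.001 on the
recovery median — small relative to the properties being asserted — while
the whole suite runs in seconds.

## Known limitations

* Fixed-effects only; heterogeneous cohorts will be over-confidently
  combined and no Q/I² statistic flags this.
* One SNP per test: no multi-instrument (multi-SNP SMR or IVW-MR across
  instruments) estimate, and `per_pair` results for one gene are
  correlated when instruments are in LD in real data.
* The shared-instrument gene network is bookkeeping over significant
  results (genes linked by the count of shared significant instrument
  SNPs); it is not an interaction or co-expression network and carries no
  biological edge semantics.
* The Eq-8 standardized scale assumes the eQTL phenotype was
  variance-standardized; effects from unstandardized pipelines will be on
  a different scale (the test statistic, being Z-based, is unaffected).
* The Wald-ratio estimate is slightly biased upward (≈ +2% at these
  conditions) because se_zx shrinks with |z| in the standardized-effect
  formula; the recovery test bands account for this.
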