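# Methods

This package implements a rare-variant-inclusive polygenic risk score (PRS)
construction pipeline of the clumping-and-thresholding-with-ensemble family,
plus a carrier-aware evaluation battery, and exercises both end to end on
synthetic genotype data. This note records the models, the defaults and the
reasoning behind the genuinely open design choices.

## Score construction

**Inputs.** GWAS summary statistics on the log-odds scale (METAL-style TSV),
an LD reference panel of dosages, and a tuning cohort with case/control
status and covariates (sex, age, BMI, principal components). Variants are
identified by `chrom:pos:ref:alt` keys with 1-based positions; records are
harmonized to the panel's alt allele (beta negated and frequency
complemented when the effect allele is the panel ref; mismatches dropped and
counted). The panel drops variants with minor allele count below 3;
individuals related at PI_HAT > 0.1875 are pruned by iterative
maximum-degree deletion of the relatedness graph (ties to the
lexicographically smallest ID). This greedy rule is deterministic; the test
suite verifies it equals the brute-force minimum vertex cover on structured
small graphs (paths, cycles, stars, cliques, bowties) and is within one
removal of optimal on random small graphs — exact minimality is not
guaranteed by max-degree deletion in general.

**Clumping grid.** Records with p >= 5e-4 are discarded (strict
inequality). Greedy clumping then runs over a grid of r-squared thresholds
(0.01, 0.05, 0.1, 0.2, 0.5, 0.8) crossed with base windows (50, 100 kb),
where each setting's effective window is `base / r2` (62.5 kb to 10,000 kb),
so looser LD thresholds search wider windows. The smallest-p unclaimed
variant becomes a lead and claims all unclaimed variants within the window
with r-squared at or above the threshold; ties at equal p break on genomic
position then variant key, making the result independent of record order.
r-squared is the squared Pearson correlation of dosages over
pairwise-complete individuals; an undefined value (monomorphic partner)
never claims a variant.

**Effect-size matrix and shrinkage.** The union of leads across the 12
settings forms the matrix rows; entry (v, s) is the estimated log-odds when
v leads under setting s and 0 otherwise, so a variant clumped away under a
setting contributes nothing to that setting's score. Effects are calibrated
with univariate normal-normal empirical-Bayes shrinkage:
`tau2 = max(0, var(beta_hat) - mean(se^2))` (method of moments, sample
variance with ddof=1 over the matrix rows) and
`beta_EB = beta_hat * tau2 / (tau2 + se^2)`. In the limit se -> 0 the
estimate is untouched; when the observed spread is explained by sampling
noise everything shrinks to zero. A multi-population covariance version of
this calibration exists in the literature; the univariate reduction is the
appropriate form for a single set of summary statistics and is validated by
a Monte-Carlo MSE-dominance check.

**Candidate scores and stacking.** Nine p-value thresholds (5e-11 through
5e-4 in half-decade steps, plus 5e-3) cross the 12 settings into 108
candidate scores per individual: `score(i; s, t) = sum_v dosage(i,v) *
beta_EB(v) * [v leads in s] * [p_v < t]`. Missing dosages mean-impute at
2 x EAF. The grid is configurable; the ninth threshold extends the
half-decade ladder upward because the prescribed count is nine while the
natural ladder from 5e-11 to 5e-4 has eight rungs. Candidates are ranked by
the AUC of logistic(case ~ score + covariates) on the tuning cohort;
candidates correlating above 0.98 (strictly) with the top performer are
dropped; the survivors are stacked with 5-fold cross-validated elastic-net
logistic regression (l1 ratio 0.5, C grid 1e-2 to 1e1). Covariates are
residualized out of the score columns before the penalized fit so covariate
signal cannot leak into variant weights; exactly identical columns
(identical supports) are collapsed onto one representative before fitting.
All randomness (fold assignment, solver) derives from the single pipeline
seed.

**Final weights.** The stacking coefficients collapse onto per-variant
weights, `final_weight(v) = beta_EB(v) * sum_k w_k [v in support_k]`, so the
distributable weight table satisfies, exactly up to float error,
`dosages @ final_weight = sum_k w_k * score_k` for any cohort. This identity
is asserted on every pipeline run and is the package's invariant connecting
the table to the ensemble.

## Evaluation battery

All metrics operate on the score standardized to mean 0, SD 1 within the
evaluation cohort.

- **Incremental AUC**: AUC(case ~ PRS + covariates) minus
  AUC(case ~ covariates), both from in-sample fitted probabilities — the
  evaluation cohort is a single held-out test set, so no further splitting
  is done. An iAUC can be mildly negative by overfitting; the suite asserts
  positivity only in expectation under true signal.
- **DeLong test** for two correlated AUCs via placement values, two-sided
  normal p; degenerate variance reports p = 1 when the AUCs agree. The
  implementation is hand-written (no installed package provides it) and
  oracle-checked against a stratified bootstrap SE and a type-I calibration
  suite.
- **OR per SD** from logistic(case ~ PRS + covariates), Wald 95% CI;
  quasi-separation is flagged with an unbounded CI.
- **Percentile-bin ORs**: each listed bin (0-2.5 through 97.5-100,
  overlapping tails included) is compared independently against the fixed
  40-60th percentile reference. Bin membership uses ordinal-rank percentiles
  (ties broken deterministically by position) so bins hold their nominal
  share even for a discrete-valued score; a bin under 10 individuals is
  flagged rather than fitted.
- **Carrier statistics**: rare-variant carriers are defined by the selection
  rule MAF < 0.03, |log-odds| > 0.3, and p < 1e-6 inside MODY gene regions
  or p < 1e-9 outside (strict inequalities; the region file is 1-based
  inclusive, deliberately not BED half-open). Carrier vs non-carrier PRS
  distributions are compared by Wilcoxon rank-sum (exact below a combined n
  of 50 without ties, tie-corrected normal approximation otherwise), and the
  estimated mean carrier odds ratio is
  `exp(mean(carrier standardized PRS) x log(OR per SD))` — the logarithmic
  reading of the published formula, the only one under which an average
  individual (PRS 0) maps to OR 1.
- **Carrier-enrichment resampling**: each iteration keeps all carriers and
  samples non-carriers without replacement so the sample totals 4x the
  carriers when there are fewer than 20 carriers, else 2x; the mean and SD
  of the incremental AUC over 100 iterations are reported. (The source
  texts disagree between a 20- and a 30-carrier cutoff; the 20-carrier
  convention with "20 or more -> 2x" is adopted.)
- **Age of onset**: linear model of age at diagnosis on the standardized
  PRS with covariates among cases (years per PRS SD).

## Synthetic data generator

The generator is first-class, tested code; it supplies every input the
pipeline needs with the statistical structure the method assumes.

**Genotypes.** Haplotypes arise from latent Gaussians with AR(1) correlation
`block_rho` within independent blocks, thresholded at the per-variant,
per-subpopulation alt-allele frequency; two haplotypes sum to a dosage.
This yields Hardy-Weinberg-consistent genotypes with tunable r-squared decay
along each block (verified against a 10^6-draw simulation of the bivariate
threshold model). Alt frequencies are drawn log-uniformly over `maf_range`
(default 1e-4 to 0.5, reaching rare variation); across subpopulations they
drift by a Balding-Nichols beta draw controlled by `fst_like_divergence`
(default 0.02 over 2 subpopulations). Chosen variants can be pinned to fixed
(per-subpopulation) frequencies, which is how the large-effect rare variants
are placed. A `related_fraction` (default 1%) of individuals is rewritten to
share haplotypes with a partner, with PI_HAT recorded near 0.5 or 0.25, to
exercise relatedness pruning.

**Phenotypes.** Liability = sqrt(h2) x standardized log-odds-weighted
genetic score + fixed covariate effects (0.10 sex, 0.20 age, 0.25 BMI on
standardized scales) + Gaussian noise filling the variance to 1. Case
status thresholds at the liability distribution's own 1 - prevalence
quantile: with a large-effect rare variant the liability is visibly
non-Gaussian, and the empirical quantile keeps the case fraction at the
nominal prevalence. Age at onset (cases only) is 58 - 5 x liability plus
N(0, 7) noise, truncated to [20, 85] years — the minimal model supporting
the onset-association stage. Because effect sizes enter on the liability
scale after standardization, the realized carrier odds ratio is an
amplified transform of the nominal log-odds whenever the total genetic
variance is small; the tests therefore verify internal consistency (a
moderate cohort's carrier OR against a brute-force logistic fit on a much
larger simulation) rather than numeric equality with the nominal odds
ratio.

**Summary statistics.** Analytic mode draws `beta_hat ~ N(beta, se^2)` with
the closed-form score-test standard error
`se = 1/sqrt(2 p (1-p) N phi (1-phi))` (phi the discovery case fraction) and
a two-sided Wald p; the effect-allele frequency equals the panel frequency
exactly. Cohort mode runs an actual per-variant score test on a simulated
discovery cohort. Monomorphic variants are emitted with missing statistics
and counted. Analytic mode deliberately omits LD convolution of marginal
effects — each variant's estimate centers on its own causal effect — which
keeps the generative truth legible to the tests.

**Default study conditions.** 900 variants in 45 blocks of 20
(`block_rho` 0.9, 25 kb spacing, 500 kb inter-block gaps), an 800-individual
reference panel, a 3,500-individual tuning cohort and a 10,000-individual
test cohort, discovery statistics at 60,000 cases / 240,000 controls,
liability h2 0.5, prevalence 0.3. The causal architecture holds 20 moderate
common effects (log-odds SD 0.08), 300 small common effects (SD 0.025, many
of which straddle the significance thresholds and thereby differentiate the
p-value grid), and nine large-effect rare variants: a MODY-class risk
variant at log-odds 2.067 (OR 7.9) and MAF 0.005; a population-specific
variant at log-odds 0.307 (OR 1.36) with subpopulation frequencies
0.002/0.010; five further risk and two protective variants with |log-odds|
0.40-0.80 at MAF 0.006. Rare variants sit in blocks carrying no other
causal variant, so the common-variant background cannot tag them through
within-block LD — the synthetic analogue of rare alleles absent from
common-variant SNP lists. Rare MAFs are set well below the 0.01 boundary of
the common-restricted baseline (so finite-panel frequency drift cannot leak
them into it) yet high enough to yield hundreds of carriers at n = 10,000;
the real counterparts can be far rarer (the published MODY example has MAF
3e-5), which a desk-scale cohort cannot represent with any carriers at all.
Cohort and discovery sample sizes are scaled-down stand-ins for the
originals (8,147 tuning; 50,918 test; 1.2 million discovery), chosen so the
full study runs in seconds per seed.

**What the generator does not emulate.** Realistic human demography and
recombination maps, imputation error, strand ambiguity, multi-ancestry
meta-analysis mechanics, LD-convolved marginal effects, and realistic
polygenicity (hundreds rather than millions of causal variants). Because a
toy panel concentrates score variance on few variants, OR-per-SD values and
rare-carrier estimated ORs come out larger than real-cohort values; passing
tests demonstrate the mechanism and the algebra, not field-realistic effect
magnitudes.

## Numerical choices and degenerate inputs

- Strict inequalities at every printed threshold (pre-filter, rare-variant
  rule, correlation pruning "more than 0.98", PI_HAT "greater than
  0.1875"); the MAC filter removes "below 3", so MAC 3 is retained.
- MAF is always min(eaf, 1 - eaf) computed after harmonization.
- Zero-variance candidate scores rank like any other column (their AUC is
  the covariate model's), survive pruning (undefined correlation never
  excludes), and receive stacking weight 0.
- Logistic fits for AUC purposes use a lightly ridged solver
  (newton-cholesky, C = 1e4) so perfect separation cannot crash a metric;
  inferential fits (OR/SD, percentile bins) use maximum likelihood and flag
  separation instead of failing.
- Empty record sets after the pre-filter are a hard error naming the stage;
  an empty clumping input yields an empty set (not an error).
- All randomness flows from one integer seed through named streams
  (panel/tuning/test/summary-statistics), so every artifact is a pure
  function of (config, seed).

## Known limitations

- The stacking learner is elastic-net logistic regression; the published
  pipeline used a stacking library whose default learner class this
  matches, but coefficients are not constrained to be non-negative and can
  differ from that implementation in detail.
- The empirical-Bayes step is the univariate reduction described above, not
  the two-dimensional multi-population calibration.
- In-sample AUCs modestly flatter every score; comparisons between scores
  (the quantity of interest) share the bias.
- The common-restricted baseline arm is a stand-in for HapMap3-style
  common-variant scores, produced by re-running the same pipeline on
  MAF >= 0.01 records rather than by an external method.
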