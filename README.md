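# rareprs

Rare-variant-inclusive polygenic risk score (PRS) construction and
carrier-aware evaluation, exercised end to end on synthetic genotype data.

Most polygenic scores for common disease are built from common variants
(MAF >= 0.01) only: rare and population-specific alleles are absent from the
usual summary statistics and LD reference panels, so the substantial risk
carried by, for example, a rare MODY-gene variant with an odds ratio near 8
is invisible to the score. This package implements, as a tested reusable
pipeline, a clumping-and-thresholding construction that keeps rare variants
in play — provided the summary statistics and the LD panel include them —
and an evaluation framework focused on what that buys for carriers of
large-effect rare alleles. It is aimed at statistical geneticists who want
the mechanism on the desk: every stage is a library function, every input
can be simulated, and the whole study runs in seconds.

## The method

Given harmonized log-odds summary statistics, an LD reference panel
(MAC >= 3, relatedness pruned at PI_HAT > 0.1875), and a tuning cohort:

1. **Pre-filter** records at p < 5e-4.
2. **Clumping grid**: greedy clumping under 12 LD settings — r-squared
   thresholds {0.01, 0.05, 0.1, 0.2, 0.5, 0.8} x base windows {50, 100} kb,
   with the effective window scaled inversely with the LD threshold,
   `window = base / r2` (62.5 kb ... 10,000 kb).
3. **Effect-size matrix**: rows are the union of lead variants, columns the
   12 settings; a variant clumped away under a setting gets effect 0 there.
4. **Empirical-Bayes calibration**: normal-normal method-of-moments
   shrinkage, `beta_EB = beta_hat * tau2 / (tau2 + se^2)` with
   `tau2 = max(0, var(beta_hat) - mean(se^2))`.
5. **Candidate scores**: 9 p-value thresholds (5e-11 ... 5e-4, plus 5e-3)
   x 12 settings = 108 scores per individual.
6. **Ensemble**: rank candidates by covariate-adjusted AUC on the tuning
   cohort, drop near-duplicates of the top score (r > 0.98), stack the rest
   with cross-validated elastic-net logistic regression, and collapse onto a
   single distributable weight table,
   `final_weight(v) = beta_EB(v) * sum_k w_k [v in support_k]`,
   which reproduces the stacked score exactly:
   `dosages @ final_weight = sum_k w_k score_k`.

Evaluation covers incremental AUC over a covariate model, DeLong tests
between scores, OR per SD, percentile-bin ORs against the 40-60th percentile
reference, Wilcoxon comparisons of carrier vs non-carrier score
distributions with the estimated mean carrier OR
`exp(mean(carrier PRS) x log(OR/SD))`, carrier-enrichment iAUC resampling
(100 iterations; 4x/2x sampling around a 20-carrier cutoff), and
age-of-onset association. `docs/methods.md` has the full model description;
the synthetic-data generator (LD-block genotypes, liability-threshold
phenotypes, analytic or cohort-mode summary statistics) is documented there
too.

## Worked example

The numbered drivers under `analysis/` run the default synthetic study: a
900-variant genome in 45 LD blocks over two subpopulations, 320 common
causal effects, and nine large-effect rare variants — including a MODY-class
risk allele at log-odds 2.07 (OR ~7.9, MAF 0.005) and a population-specific
allele at log-odds 0.307 (OR ~1.36) carried at 1.0% in one subpopulation and
0.2% in the other. Two scores are trained from the same summary statistics:
the rare-variant-inclusive score, and a baseline restricted to MAF >= 0.01
records (the stand-in for a common-variant-only score).

```sh
cd analysis
python 01_simulate_data.py     # fixtures -> scratch/fixtures, summary -> results/
python 02_train_scores.py      # weight tables -> results/weights_*.tsv
python 03_evaluate_scores.py   # iAUC, OR/SD, percentile ORs, DeLong
python 04_carrier_analysis.py  # carrier statistics and enrichment iAUC
```

Output of the evaluation and carrier stages at seed 0:

```
inclusive: AUC 0.834 (covariates 0.659, iAUC 0.175), OR/SD 5.25 [4.84-5.69]
common_restricted: AUC 0.788 (covariates 0.659, iAUC 0.129), OR/SD 2.89 [2.73-3.07]
DeLong inclusive vs common-restricted (PRS-only AUC): 0.788 vs 0.739, p = 2.72e-48

inclusive: 686 risk carriers, mean estimated OR 23.38, Wilcoxon p 1.8e-295,
           enrichment iAUC 0.250 +/- 0.010
common_restricted: 686 risk carriers, mean estimated OR 0.97, Wilcoxon p 0.53,
           enrichment iAUC 0.099 +/- 0.009
```

Reading: both scores predict case status well beyond the covariates, but
only the inclusive score separates carriers of rare risk variants from
non-carriers — the common-restricted score assigns carriers an estimated
mean OR indistinguishable from 1 (it cannot see alleles absent from its
input), while the inclusive score assigns them a strongly elevated OR and
wins the carrier-enrichment iAUC comparison by an order of magnitude. At
this toy scale the score variance is concentrated on a few hundred
variants, so OR magnitudes are amplified relative to biobank-scale values;
the contrast between the arms, not the absolute numbers, is the result.

## Layout

```
src/rareprs/        the library: sumstats, ldpanel, core (clumping grid,
                    EB, scoring), ensemble, evaluate, simulate, pipeline,
                    experiments, io, cli
analysis/           numbered drivers for the synthetic study
tests/              pytest suite incl. acceptance tests and test oracles
scripts/acceptance.py
docs/methods.md     models, defaults, design rationale, limitations
```

A thin CLI (`rareprs simulate|train|score|evaluate`) wraps the pipeline for
shell use; every constant lives in a YAML config (see
`rareprs.pipeline.PipelineConfig`) rather than being hard-coded.
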