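"""Evaluation battery: iAUC, DeLong, OR/SD, percentile ORs, carrier tests,
enrichment resampling and age-of-onset association."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rareprs.evaluate import (
    PERCENTILE_BINS,
    EnrichmentSpec,
    age_onset_assoc,
    carrier_distribution_test,
    delong_test,
    enrichment_sample,
    incremental_auc,
    or_per_sd,
    percentile_or,
    standardize_prs,
)


def _cov(rng, n):
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(55, 8, n),
            "bmi": rng.normal(28, 5, n),
            "PC1": rng.normal(0, 1, n),
        }
    )


def _logistic_world(rng, n, beta_prs=0.7, cov_effect=0.4):
    prs = rng.standard_normal(n)
    cov = _cov(rng, n)
    z_age = (cov["age"] - 55) / 8
    lin = -1.0 + beta_prs * prs + cov_effect * z_age
    y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
    return prs, y, cov


class TestIncrementalAUC:
    def test_prs_equal_to_covariate_fit_adds_nothing(self, rng):
        import statsmodels.api as sm

        n = 3000
        _, y, cov = _logistic_world(rng, n, beta_prs=0.0)
        X = sm.add_constant((cov - cov.mean()) / cov.std())
        probs = sm.Logit(y, X).fit(disp=0).predict()
        auc_full, auc_cov, iauc = incremental_auc(probs, y, cov)
        assert abs(iauc) < 1e-3

    def test_perfectly_separating_prs_reaches_auc_one(self, rng):
        n = 500
        y = rng.integers(0, 2, n)
        prs = y + 0.01 * rng.random(n)
        auc_full, _, _ = incremental_auc(prs, y, _cov(rng, n))
        assert auc_full == pytest.approx(1.0, abs=1e-9)

    def test_auc_matches_pairwise_enumeration_on_hand_dataset(self, rng):
        """Covariate-free AUC equals the exhaustive case-control pair count
        (Mann-Whitney statistic) on a 20-row dataset."""
        n = 20
        prs = rng.standard_normal(n)
        y = np.array([1] * 8 + [0] * 12)
        # constant covariates so the model reduces to the PRS alone
        cov = pd.DataFrame({"c": np.zeros(n)})
        auc_full, _, _ = incremental_auc(prs, y, cov)
        wins = ties = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                wins += prs[i] > prs[j]
                ties += prs[i] == prs[j]
        expect = (wins + 0.5 * ties) / (8 * 12)
        assert auc_full == pytest.approx(expect, abs=1e-12)

    def test_single_class_is_hard_error(self, rng):
        with pytest.raises(ValueError):
            incremental_auc(rng.standard_normal(50), np.zeros(50), _cov(rng, 50))


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        n = 300
        probs = rng.random(n)
        y = rng.integers(0, 2, n)
        res = delong_test(probs, probs, y)
        assert res.auc_a == res.auc_b
        assert res.p == 1.0

    def test_se_agrees_with_stratified_bootstrap(self, rng):
        """DeLong SE of the AUC difference within 15% of a 2000-replicate
        stratified bootstrap SE."""
        n = 200
        liability = rng.standard_normal(n)
        y = (liability + rng.standard_normal(n) > 0).astype(int)
        a = liability + 0.8 * rng.standard_normal(n)
        b = liability + 1.2 * rng.standard_normal(n)
        res = delong_test(a, b, y)

        def auc(score, yy):
            r = stats.rankdata(score)
            m = yy.sum()
            return (r[yy == 1].sum() - m * (m + 1) / 2) / (m * (len(yy) - m))

        cases = np.flatnonzero(y == 1)
        controls = np.flatnonzero(y == 0)
        boot_rng = np.random.default_rng(7)
        diffs = []
        for _ in range(2000):
            idx = np.concatenate(
                [
                    boot_rng.choice(cases, size=len(cases), replace=True),
                    boot_rng.choice(controls, size=len(controls), replace=True),
                ]
            )
            diffs.append(auc(a[idx], y[idx]) - auc(b[idx], y[idx]))
        boot_se = np.std(diffs, ddof=1)
        assert res.se_diff == pytest.approx(boot_se, rel=0.15)

    def test_misaligned_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_test(rng.random(10), rng.random(9), rng.integers(0, 2, 10))


class TestORPerSD:
    def test_recovers_true_coefficient(self, rng):
        """True OR per SD of 2 recovered within [1.9, 2.1] nearly always."""
        hits = 0
        reps = 30
        for _ in range(reps):
            prs, y, cov = _logistic_world(rng, 20_000, beta_prs=np.log(2))
            res = or_per_sd(prs, y, cov)
            hits += 1.9 <= res.or_per_sd <= 2.1
        assert hits >= 0.9 * reps

    def test_scale_invariance(self, rng):
        prs, y, cov = _logistic_world(rng, 2000)
        a = or_per_sd(prs, y, cov)
        b = or_per_sd(10 * prs, y, cov)
        assert a.or_per_sd == pytest.approx(b.or_per_sd, rel=1e-8)

    def test_null_ci_covers_one(self, rng):
        cover = 0
        reps = 300
        for _ in range(reps):
            prs, y, cov = _logistic_world(rng, 800, beta_prs=0.0)
            res = or_per_sd(prs, y, cov)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert abs(cover / reps - 0.95) <= 0.03


class TestPercentileOR:
    def test_reference_bin_or_is_one(self, rng):
        prs, y, cov = _logistic_world(rng, 3000)
        out = percentile_or(prs, y, cov, bins=((40, 60),))
        assert out["or"].iloc[0] == 1.0

    def test_monotone_bins_under_strong_signal(self, rng):
        prs, y, cov = _logistic_world(rng, 50_000, beta_prs=np.log(2))
        bins = ((0, 10), (10, 20), (20, 30), (30, 40), (60, 70), (80, 90), (90, 100))
        out = percentile_or(prs, y, cov, bins=bins)
        ors = out["or"].to_numpy()
        assert np.all(np.diff(ors) > 0)

    def test_overlapping_tail_bins_reported_separately(self, rng):
        prs, y, cov = _logistic_world(rng, 8000, beta_prs=np.log(2))
        out = percentile_or(prs, y, cov)
        assert len(out) == len(PERCENTILE_BINS)
        tails = out[out["pct_low"] == 0]
        assert len(tails) == 3  # 0-2.5, 0-5, 0-10 each vs the same reference

    def test_small_bin_flagged(self, rng):
        prs, y, cov = _logistic_world(rng, 200)
        out = percentile_or(prs, y, cov, bins=((0, 2.5),), min_count=10)
        assert bool(out["flagged"].iloc[0])


class TestCarrierTest:
    def test_printed_formula(self):
        # carriers' mean standardized PRS 0.5 at OR/SD 2 -> mean OR = 2^0.5
        prs = np.array([0.5, 0.5, -0.1, 0.1, 0.0, 0.0])
        flag = np.array([True, True, False, False, False, False])
        res, per_ind = carrier_distribution_test(prs, flag, 2.0)
        assert res.mean_estimated_or == pytest.approx(np.sqrt(2))
        np.testing.assert_allclose(per_ind, 2.0**prs)

    def test_random_flags_give_uniform_p(self, rng):
        rejects = 0
        reps = 400
        prs = standardize_prs(rng.standard_normal(500))
        for _ in range(reps):
            flag = rng.random(500) < 0.1
            if not flag.any() or flag.all():
                continue
            res, _ = carrier_distribution_test(prs, flag, 2.0)
            rejects += res.wilcoxon_p < 0.05
        assert abs(rejects / reps - 0.05) <= 0.025

    def test_no_carriers_is_hard_error(self):
        with pytest.raises(ValueError):
            carrier_distribution_test(np.zeros(10), np.zeros(10, bool), 2.0)

    def test_exact_method_below_50(self, rng):
        prs = rng.standard_normal(30)
        flag = np.zeros(30, bool)
        flag[:5] = True
        res, _ = carrier_distribution_test(prs, flag, 2.0)
        exact = stats.mannwhitneyu(
            prs[flag], prs[~flag], alternative="two-sided", method="exact"
        )
        assert res.wilcoxon_p == pytest.approx(exact.pvalue)


class TestEnrichment:
    def test_sample_sizes_by_carrier_count(self, rng):
        spec = EnrichmentSpec(iterations=3, seed=1)
        for n_car, expect in ((15, 60), (30, 60)):
            n = 2000
            prs, y, cov = _logistic_world(rng, n)
            flag = np.zeros(n, bool)
            flag[:n_car] = True
            res = enrichment_sample(prs, y, cov, flag, spec)
            assert res.sample_size == expect

    def test_deterministic_given_seed(self, rng):
        n = 1000
        prs, y, cov = _logistic_world(rng, n)
        flag = np.zeros(n, bool)
        flag[:25] = True
        spec = EnrichmentSpec(iterations=5, seed=9)
        a = enrichment_sample(prs, y, cov, flag, spec)
        b = enrichment_sample(prs, y, cov, flag, spec)
        assert a.iaucs == b.iaucs

    def test_insufficient_noncarriers_is_hard_error(self, rng):
        n = 50
        prs, y, cov = _logistic_world(rng, n)
        flag = np.ones(n, bool)
        flag[-5:] = False
        with pytest.raises(ValueError, match="non-carriers"):
            enrichment_sample(prs, y, cov, flag, EnrichmentSpec(iterations=2, seed=0))

    def test_multiplier_must_hold_all_carriers(self):
        with pytest.raises(ValueError):
            EnrichmentSpec(total_multiplier_large=1)


class TestAgeOnset:
    def _onset_world(self, rng, n, slope=-0.6):
        prs = standardize_prs(rng.standard_normal(n))
        cov = _cov(rng, n)
        onset = 55 + slope * prs + 0.5 * ((cov["age"] - 55) / 8) + rng.normal(0, 5, n)
        return prs, onset.to_numpy(), cov

    def test_recovers_slope(self, rng):
        prs, onset, cov = self._onset_world(rng, 10_000, slope=-0.6)
        res = age_onset_assoc(prs, onset, cov)
        assert res.beta_per_sd == pytest.approx(-0.6, abs=0.2)

    def test_null_p_uniform(self, rng):
        rejects = 0
        reps = 300
        for _ in range(reps):
            prs, onset, cov = self._onset_world(rng, 300, slope=0.0)
            res = age_onset_assoc(prs, onset, cov)
            rejects += res.p < 0.05
        assert abs(rejects / reps - 0.05) <= 0.03

    def test_translation_invariance(self, rng):
        prs, onset, cov = self._onset_world(rng, 2000)
        a = age_onset_assoc(prs, onset, cov)
        b = age_onset_assoc(prs, onset + 10.0, cov)
        assert a.beta_per_sd == pytest.approx(b.beta_per_sd, rel=1e-9)

    def test_too_few_cases_is_hard_error(self, rng):
        prs, onset, cov = self._onset_world(rng, 40)
        onset[20:] = np.nan
        with pytest.raises(ValueError, match="age at onset"):
            age_onset_assoc(prs, onset, cov)


class TestSignalIAUC:
    def test_mean_iauc_positive_when_prs_informative(self, rng):
        """With true signal beyond covariates, iAUC averages positive."""
        iaucs = []
        for _ in range(20):
            prs, y, cov = _logistic_world(rng, 1500, beta_prs=0.5)
            _, _, iauc = incremental_auc(prs, y, cov)
            iaucs.append(iauc)
        assert np.mean(iaucs) > 0
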