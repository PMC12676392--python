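"""Generator correctness: determinism, HWE, LD, phenotypes, summary stats."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from rareprs.simulate import (
    CausalArchitecture,
    RareEffect,
    SimulationConfig,
    default_scenario,
    generate_summary_stats,
    simulate_cohort,
    simulate_genotypes,
    simulate_panel,
    simulate_phenotypes,
    variant_keys,
)


def _config(**kw):
    base = dict(
        n_variants=60, n_blocks=3, block_rho=0.5, maf_range=(0.01, 0.5),
        n_subpops=1, fst_like_divergence=0.0, seed=7, n_ref_individuals=500,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            _config(n_variants=0)
        with pytest.raises(ValueError):
            _config(block_rho=1.0)
        with pytest.raises(ValueError):
            _config(maf_range=(0.0, 0.5))

    def test_block_sizes_sum_to_n_variants(self):
        cfg = _config(n_variants=61)
        assert cfg.block_sizes().sum() == 61


class TestPanel:
    def test_same_seed_bit_identical(self):
        a = simulate_panel(_config())
        b = simulate_panel(_config())
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert list(a.variants["variant_key"]) == list(b.variants["variant_key"])

    def test_different_seed_differs(self):
        a = simulate_panel(_config())
        b = simulate_panel(_config(seed=8))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_rho_zero_gives_near_zero_r2(self):
        cfg = _config(block_rho=0.0, n_ref_individuals=2000)
        panel = simulate_panel(cfg)
        d = panel.dosages
        r2s = []
        for j in range(0, 19):
            a, b = d[:, j], d[:, j + 1]
            if a.std() == 0 or b.std() == 0:
                continue
            r2s.append(np.corrcoef(a, b)[0, 1] ** 2)
        assert np.mean(r2s) < 0.02

    def test_hwe_genotype_frequencies(self):
        cfg = _config(n_ref_individuals=4000, maf_range=(0.1, 0.5))
        panel = simulate_panel(cfg)
        n = panel.n_individuals
        for j in range(0, panel.n_variants, 7):
            d = panel.dosages[:, j]
            p = d.mean() / 2
            if p < 0.05 or p > 0.95:
                continue
            expected = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
            observed = np.array([(d == k).sum() for k in (0, 1, 2)])
            chi2 = ((observed - expected) ** 2 / expected).sum()
            # 1 df after frequency estimation; bound generous at many variants
            assert chi2 < stats.chi2.ppf(0.999, 1)

    def test_adjacent_r2_matches_large_sample_oracle(self):
        """Empirical r2 of adjacent common variants under block_rho = 0.9
        agrees with a direct large-sample simulation of the bivariate
        threshold model at the same frequencies."""
        rho = 0.9
        freq = (0.3, 0.4)
        cfg = _config(
            n_variants=2, n_blocks=1, block_rho=rho, n_ref_individuals=2000,
            freq_overrides={0: (freq[0],), 1: (freq[1],)},
        )
        panel = simulate_panel(cfg)
        obs = np.corrcoef(panel.dosages[:, 0], panel.dosages[:, 1])[0, 1] ** 2

        oracle_rng = np.random.default_rng(123)  # independent implementation
        n = 1_000_000
        cov = np.array([[1, rho], [rho, 1]])
        L = np.linalg.cholesky(cov)
        h1 = oracle_rng.standard_normal((n, 2)) @ L.T
        h2 = oracle_rng.standard_normal((n, 2)) @ L.T
        thr = stats.norm.ppf(freq)
        d = (h1 < thr).astype(float) + (h2 < thr)
        expect = np.corrcoef(d[:, 0], d[:, 1])[0, 1] ** 2
        assert obs == pytest.approx(expect, abs=0.05)

    def test_position_metadata_one_based_and_sorted(self):
        panel = simulate_panel(_config())
        pos = panel.variants["pos"].to_numpy()
        assert pos[0] == 1
        assert np.all(np.diff(pos) > 0)


class TestPhenotypes:
    def _arch(self, keys, h2=0.5, prevalence=0.3, rare_beta=2.07):
        common = {keys[5]: 0.15, keys[25]: -0.12, keys[45]: 0.1}
        rare = {keys[15]: RareEffect(beta=rare_beta, gene_class="mody")}
        return CausalArchitecture(
            common_effects=common, rare_effects=rare,
            liability_h2=h2, prevalence=prevalence,
        )

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            CausalArchitecture(liability_h2=1.2)
        with pytest.raises(ValueError):
            CausalArchitecture(prevalence=0.0)

    def test_case_fraction_matches_prevalence(self):
        cfg = _config()
        keys = variant_keys(cfg)
        arch = self._arch(keys, prevalence=0.3)
        cohort = simulate_cohort(cfg, arch, 10_000, stream=5)
        se = np.sqrt(0.3 * 0.7 / 10_000)
        assert abs(cohort.phenotype.mean() - 0.3) < 3 * se

    def test_h2_zero_phenotype_independent_of_genotype(self):
        cfg = _config()
        keys = variant_keys(cfg)
        arch = self._arch(keys, h2=0.0)
        cohort = simulate_cohort(cfg, arch, 6_000, stream=5)
        g = cohort.dosages @ arch.beta_vector(keys)
        r = np.corrcoef(g, cohort.phenotype)[0, 1]
        assert abs(r) < 3 / np.sqrt(cohort.n)

    def test_carrier_odds_ratio_consistent_with_large_sample_fit(self):
        """The realized carrier odds ratio in a moderate cohort agrees with a
        brute-force logistic fit on a much larger simulation of the same
        generative model (within joint Monte-Carlo error)."""
        import statsmodels.api as sm

        cfg = _config(freq_overrides={15: (0.02,)})
        keys = variant_keys(cfg)
        arch = self._arch(keys, rare_beta=2.07)
        j = 15

        def carrier_logodds(n, stream):
            cohort = simulate_cohort(cfg, arch, n, stream=stream)
            x = (cohort.dosages[:, j] > 0.5).astype(float)
            fit = sm.Logit(cohort.phenotype, sm.add_constant(x)).fit(disp=0)
            return fit.params[1], fit.bse[1]

        b_small, se_small = carrier_logodds(20_000, stream=6)
        b_big, se_big = carrier_logodds(300_000, stream=7)
        assert abs(b_small - b_big) < 3 * np.hypot(se_small, se_big)

    def test_age_at_onset_cases_only_and_in_range(self):
        cfg = _config()
        arch = self._arch(variant_keys(cfg))
        cohort = simulate_cohort(cfg, arch, 3_000, stream=5)
        cases = cohort.phenotype == 1
        assert np.all(np.isfinite(cohort.age_at_onset[cases]))
        assert np.all(np.isnan(cohort.age_at_onset[~cases]))
        on = cohort.age_at_onset[cases]
        assert on.min() >= 20 and on.max() <= 85

    def test_relatedness_pairs_recorded_with_expected_pihat(self):
        cfg = _config(related_fraction=0.05)
        arch = self._arch(variant_keys(cfg))
        cohort = simulate_cohort(cfg, arch, 2_000, stream=5)
        assert len(cohort.relatedness_pairs) == 50
        for a, b, pihat in cohort.relatedness_pairs:
            assert a != b
            assert 0.15 < pihat < 0.6


class TestSummaryStats:
    def test_type_one_error_calibration_under_null(self):
        cfg = _config(n_variants=1000, n_blocks=1000, block_rho=0.0,
                      maf_range=(0.2, 0.5), n_ref_individuals=400)
        panel = simulate_panel(cfg)
        arch = CausalArchitecture()  # no causal effects
        res = generate_summary_stats(panel, arch, 5_000, 20_000, seed=3)
        ps = np.array([r.p for r in res.records if np.isfinite(r.p)])
        frac = (ps < 0.05).mean()
        assert abs(frac - 0.05) <= 0.02

    def test_analytic_betahat_unbiased(self):
        """Over replicate draws, mean(beta_hat) is within 3 SEM of beta."""
        cfg = _config(n_variants=2, n_blocks=1, maf_range=(0.3, 0.3),
                      n_ref_individuals=2000)
        panel = simulate_panel(cfg)
        keys = variant_keys(cfg)
        arch = CausalArchitecture(common_effects={keys[0]: 0.2})
        draws = []
        for s in range(2000):
            res = generate_summary_stats(panel, arch, 5_000, 20_000, seed=s)
            draws.append(res.records[0].beta)
        draws = np.array(draws)
        sem = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.2) < 3 * sem

    def test_rare_variant_underpowered_at_small_n(self):
        """A MAF 5e-4, OR 1.5 variant almost never reaches genome-wide
        significance at a small discovery sample — the analytic-power reason
        large meta-analyses are needed for rare variants."""
        eaf = 5e-4
        beta = np.log(1.5)
        n_case, n_control = 2_000, 8_000
        N, phi = n_case + n_control, 0.2
        se = 1 / np.sqrt(2 * eaf * (1 - eaf) * N * phi * (1 - phi))
        # analytic power at alpha 5e-8
        zcrit = stats.norm.isf(2.5e-8)
        power = stats.norm.sf(zcrit - beta / se) + stats.norm.cdf(-zcrit - beta / se)
        assert power < 0.01
        rng_hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            bhat = beta + se * rng.standard_normal()
            p = 2 * stats.norm.sf(abs(bhat) / se)
            rng_hits += p < 5e-8
        assert rng_hits <= 5

    def test_eaf_equals_panel_frequency_exactly(self):
        cfg = _config()
        panel = simulate_panel(cfg)
        res = generate_summary_stats(panel, CausalArchitecture(), 1000, 4000, seed=0)
        eafs = np.array([r.eaf for r in res.records])
        np.testing.assert_array_equal(eafs, panel.variants["eaf"].to_numpy())

    def test_monomorphic_variant_flagged(self):
        cfg = _config(maf_range=(1e-4, 1e-4), n_ref_individuals=50)
        panel = simulate_panel(cfg)
        res = generate_summary_stats(panel, CausalArchitecture(), 1000, 4000, seed=0)
        mono = (panel.variants["mac"] == 0).sum()
        assert res.n_flagged == mono
        assert mono > 0

    def test_cohort_mode_score_test_agrees_with_analytic_se(self):
        cfg = _config(n_variants=30, n_blocks=30, block_rho=0.0,
                      maf_range=(0.2, 0.5))
        arch = CausalArchitecture()
        cohort = simulate_cohort(cfg, arch, 5_000, stream=9)
        res = generate_summary_stats(
            None, arch, 0, 0, mode="cohort", cohort=cohort
        )
        # score-test se should match the closed form at the cohort's phi
        phi = cohort.phenotype.mean()
        n = cohort.n
        for r in res.records[:10]:
            pq = r.eaf * (1 - r.eaf)
            expect = 1 / np.sqrt(2 * pq * n * phi * (1 - phi))
            assert r.se == pytest.approx(expect, rel=0.1)


class TestDefaultScenario:
    def test_rare_effects_satisfy_invariants(self, scenario, world):
        panel = world["panel"]
        for key, eff in scenario.arch.rare_effects.items():
            assert abs(eff.beta) >= 0.3
            i = panel.index_of(key)
            assert panel.variants["maf"].iloc[i] < 0.03

    def test_scenario_is_deterministic(self):
        a, b = default_scenario(3), default_scenario(3)
        assert a.arch.common_effects == b.arch.common_effects
        assert a.config.freq_overrides == b.config.freq_overrides

    def test_population_specific_variant_differs_across_subpops(self, scenario):
        from rareprs.simulate import _allele_frequencies

        freqs = _allele_frequencies(scenario.config)
        key = next(iter(scenario.arch.population_specific))
        keys = variant_keys(scenario.config)
        j = keys.index(key)
        assert freqs[1, j] / freqs[0, j] > 3
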