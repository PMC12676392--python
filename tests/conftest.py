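"""Shared fixtures: the default synthetic study (simulated once per session)
and a small fast world for unit tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rareprs import pipeline as pl
from rareprs.ldpanel import apply_mac_filter
from rareprs.simulate import (
    default_scenario,
    generate_summary_stats,
    simulate_cohort,
    simulate_panel,
)
from rareprs.sumstats import harmonize, select_rare_variants

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def world(scenario):
    """Panel, cohorts, harmonized records and rare-variant calls at seed 0."""
    panel = apply_mac_filter(simulate_panel(scenario.config), 3)
    tuning = simulate_cohort(
        scenario.config, scenario.arch, scenario.n_tuning, stream=1, id_prefix="TUNE"
    )
    test = simulate_cohort(
        scenario.config, scenario.arch, scenario.n_test, stream=2, id_prefix="TEST"
    )
    res = generate_summary_stats(
        panel,
        scenario.arch,
        scenario.n_case_discovery,
        scenario.n_control_discovery,
        seed=scenario.config.seed,
    )
    records = harmonize(res.records, panel).records
    calls = select_rare_variants(records, scenario.rare_rule)
    return {
        "panel": panel,
        "tuning": tuning,
        "test": test,
        "records": records,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def trained(world, scenario):
    """Rare-variant-inclusive and common-restricted trainings at seed 0."""
    cfg = pl.PipelineConfig(seed=scenario.config.seed)
    tuning = world["tuning"]
    inclusive = pl.train_scores(
        world["records"],
        world["panel"],
        tuning.dosages,
        tuning.variant_keys,
        tuning.phenotype,
        tuning.covariates,
        cfg,
    )
    baseline = pl.train_scores(
        pl.restrict_common(world["records"], cfg.common_maf_min),
        world["panel"],
        tuning.dosages,
        tuning.variant_keys,
        tuning.phenotype,
        tuning.covariates,
        cfg,
    )
    return {"inclusive": inclusive, "baseline": baseline, "config": cfg}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
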