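"""Shared fixture loading for the analysis drivers."""

from __future__ import annotations

import json
from pathlib import Path

from rareprs import io
from rareprs.ldpanel import apply_mac_filter
from rareprs.sumstats import harmonize, read_summary_stats, select_rare_variants

_ROOT = Path(__file__).resolve().parents[1]
FIXTURE_DIR = _ROOT / "scratch" / "fixtures"
RESULTS_DIR = _ROOT / "results"


def load_fixtures(cfg, fixture_dir: Path = FIXTURE_DIR):
    """Read the simulated fixtures back from disk into pipeline inputs."""
    manifest = json.loads((fixture_dir / "manifest.json").read_text())
    files = manifest["files"]
    panel = apply_mac_filter(io.read_panel_tsv(fixture_dir / files["panel"]), cfg.min_mac)
    records = harmonize(
        read_summary_stats(fixture_dir / files["sumstats"]).records, panel
    ).records
    regions = io.read_mody_regions_tsv(fixture_dir / files["mody_regions"])
    calls = select_rare_variants(records, cfg.rare_rule(regions))

    cohorts = {}
    for which in ("tuning", "test"):
        dosages, keys, ids = io.read_dosage_tsv(fixture_dir / files[which])
        pheno = io.read_phenotypes_tsv(fixture_dir / files[f"{which}_phenotypes"])
        cohorts[which] = {
            "dosages": dosages,
            "keys": keys,
            "ids": ids,
            "phenotype": pheno["phenotype"].to_numpy(int),
            "covariates": pheno[["sex", "age", "bmi", "PC1", "PC2", "PC3", "PC4"]],
            "age_at_onset": pheno["age_at_onset"].to_numpy(float),
        }
    return manifest, panel, records, calls, cohorts
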