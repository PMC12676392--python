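#!/usr/bin/env python
"""Simulate the synthetic study and write its fixtures.

Generates the LD reference panel (800 individuals x 900 variants in 45
AR(1) blocks over two subpopulations), the tuning (n=3,500) and test
(n=10,000) cohorts with liability-threshold case/control status, and
analytic discovery summary statistics (60,000 cases / 240,000 controls).
Fixtures go to scratch/fixtures/ (regenerable, not part of the deliverable);
a small summary of the simulated world goes to results/.
"""

from __future__ import annotations

import json
import sys

import numpy as np

from common import FIXTURE_DIR, RESULTS_DIR
from rareprs import pipeline as pl
from rareprs.simulate import default_scenario


def main(seed: int = 0) -> None:
    cfg = pl.PipelineConfig(seed=seed)
    scen = default_scenario(seed)
    manifest = pl.run_simulate(cfg, FIXTURE_DIR, overwrite=True, scenario=scen)

    summary = {
        "seed": seed,
        "n_panel_variants_after_mac_filter": manifest["n_variants"],
        "n_tuning": manifest["n_tuning"],
        "n_test": manifest["n_test"],
        "n_rare_causal": len(scen.arch.rare_effects),
        "n_common_causal": len(scen.arch.common_effects),
        "liability_h2": scen.arch.liability_h2,
        "prevalence": scen.arch.prevalence,
        "rare_effects": {
            k: {"beta": v.beta, "gene_class": v.gene_class,
                "population_specific": k in scen.arch.population_specific}
            for k, v in scen.arch.rare_effects.items()
        },
    }
    RESULTS_DIR.mkdir(exist_ok=True)
    out = RESULTS_DIR / "01_simulated_world.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote fixtures to {FIXTURE_DIR} and summary to {out}")
    print(f"  {manifest['n_variants']} panel variants, "
          f"{summary['n_common_causal']} common + {summary['n_rare_causal']} rare causal effects")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
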