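#!/usr/bin/env python
"""Evaluate both weight tables on the held-out test cohort.

For each score: incremental AUC over the covariate model, OR per SD with
95% CI, percentile-bin ORs against the 40-60th percentile reference, and
the paired DeLong comparison between the two scores. Metric tables land in
results/.
"""

from __future__ import annotations

import json
import sys

from common import RESULTS_DIR, load_fixtures
from rareprs import ensemble, evaluate
from rareprs import pipeline as pl


def main(seed: int = 0) -> None:
    cfg = pl.PipelineConfig(seed=seed)
    manifest, panel, records, calls, cohorts = load_fixtures(cfg)
    test = cohorts["test"]

    prs = {}
    for name in ("inclusive", "common_restricted"):
        table = ensemble.read_score_file(RESULTS_DIR / f"weights_{name}.tsv")
        raw = ensemble.score_with_table(test["dosages"], test["keys"], table)
        prs[name] = evaluate.standardize_prs(raw)

    rows = []
    for name, p in prs.items():
        auc_full, auc_cov, iauc = evaluate.incremental_auc(
            p, test["phenotype"], test["covariates"]
        )
        orsd = evaluate.or_per_sd(p, test["phenotype"], test["covariates"])
        pct = evaluate.percentile_or(p, test["phenotype"], test["covariates"])
        pct.to_csv(RESULTS_DIR / f"03_percentile_or_{name}.tsv", sep="\t", index=False)
        rows.append(
            dict(score=name, auc_full=auc_full, auc_cov=auc_cov, iauc=iauc,
                 or_per_sd=orsd.or_per_sd, ci_low=orsd.ci_low, ci_high=orsd.ci_high)
        )
        print(f"{name}: AUC {auc_full:.3f} (covariates {auc_cov:.3f}, iAUC {iauc:.3f}), "
              f"OR/SD {orsd.or_per_sd:.2f} [{orsd.ci_low:.2f}-{orsd.ci_high:.2f}]")

    dl = evaluate.delong_test(
        prs["inclusive"], prs["common_restricted"], test["phenotype"]
    )
    print(f"DeLong inclusive vs common-restricted (PRS-only AUC): "
          f"{dl.auc_a:.3f} vs {dl.auc_b:.3f}, p = {dl.p:.3g}")

    import pandas as pd

    pd.DataFrame(rows).to_csv(RESULTS_DIR / "03_evaluation.tsv", sep="\t", index=False)
    (RESULTS_DIR / "03_delong.json").write_text(
        json.dumps({"auc_inclusive": dl.auc_a, "auc_common_restricted": dl.auc_b,
                    "p": dl.p}, indent=2) + "\n"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
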