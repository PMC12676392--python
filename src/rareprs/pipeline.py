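"""End-to-end orchestration: simulate fixtures, train a weight table, evaluate.

The pipeline stages mirror the score-construction recipe: pre-filter the
summary statistics (p < 5e-4), clump over the 12-setting LD grid, assemble
the effect-size matrix, calibrate it with empirical-Bayes shrinkage, compute
the 108 candidate scores on the tuning cohort, rank them by AUC, prune
near-duplicates of the top score (r > 0.98), stack the survivors with
elastic-net logistic regression and collapse everything into one
distributable per-variant weight table.

Each stage's hard error is re-raised as a :class:`StageError` naming the
stage. ``train_scores`` / ``evaluate_table`` work on in-memory objects; the
``run_*`` functions wrap them with fixture files for the CLI and the
analysis drivers. A common-variant-restricted baseline (the stand-in for
HapMap3-style scores) is produced by re-running training on records with
MAF >= ``common_maf_min``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core, ensemble, evaluate, io, simulate
from .ldpanel import LDPanel, RelatednessGraph, apply_mac_filter, prune_related
from .sumstats import (
    RareVariantCall,
    RareVariantRule,
    SummaryStatRecord,
    harmonize,
    prefilter,
    read_summary_stats,
    select_rare_variants,
    write_summary_stats,
)

logger = logging.getLogger("rareprs")

__all__ = [
    "PipelineConfig",
    "StageError",
    "TrainResult",
    "train_scores",
    "evaluate_table",
    "carrier_flags",
    "restrict_common",
    "run_simulate",
    "run_train",
    "run_evaluate",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, serializable to YAML.

    Defaults are the printed constants of the recipe: 5e-4 pre-filter, the
    6 x 2 clump grid, nine p-value thresholds, 0.98 correlation pruning,
    MAC >= 3 panel filter, PI_HAT > 0.1875 relatedness pruning, the
    rare-variant selection rule and 100-iteration carrier enrichment.
    """

    seed: int = 0
    out_dir: str = "scratch/pipeline"
    sumstats_path: str | None = None
    panel_path: str | None = None
    tuning_path: str | None = None
    test_path: str | None = None
    relatedness_path: str | None = None
    mody_regions_path: str | None = None

    prefilter_p: float = 5e-4
    r2_thresholds: tuple[float, ...] = core.R2_THRESHOLDS
    base_windows_kb: tuple[float, ...] = core.BASE_WINDOWS_KB
    p_thresholds: tuple[float, ...] = core.P_THRESHOLDS
    correlation_prune: float = 0.98
    min_mac: int = 3
    pi_hat_max: float = 0.1875
    common_maf_min: float = 0.01
    rare_maf_max: float = 0.03
    rare_abs_beta_min: float = 0.3
    rare_p_max_mody: float = 1e-6
    rare_p_max_other: float = 1e-9
    enrichment_iterations: int = 100
    enrichment_small_cutoff: int = 20
    cv_folds: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("r2_thresholds", "base_windows_kb", "p_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("r2_thresholds", "base_windows_kb", "p_thresholds"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def grid(self) -> tuple[core.ClumpSetting, ...]:
        return core.default_grid(self.r2_thresholds, self.base_windows_kb)

    def rare_rule(self, mody_regions=()) -> RareVariantRule:
        return RareVariantRule(
            maf_max=self.rare_maf_max,
            abs_beta_min=self.rare_abs_beta_min,
            p_max_mody=self.rare_p_max_mody,
            p_max_other=self.rare_p_max_other,
            mody_regions=tuple(mody_regions),
        )

    def enrichment_spec(self, seed: int | None = None) -> evaluate.EnrichmentSpec:
        return evaluate.EnrichmentSpec(
            small_carrier_cutoff=self.enrichment_small_cutoff,
            iterations=self.enrichment_iterations,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class TrainResult:
    """Everything the training stage produced, plus stage-count logging."""

    weight_table: pd.DataFrame
    matrix: core.EffectSizeMatrix
    clumped_sets: list[core.ClumpedVariantSet]
    candidates: pd.DataFrame
    ranked: list[ensemble.ScorePerformance]
    retained: list[tuple]
    weights: ensemble.EnsembleWeights
    stage_counts: dict = field(default_factory=dict)

    def report_json(self) -> str:
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "ranked_auc": [
                    {"setting": s, "p_threshold": t, "auc": sp.auc}
                    for sp, (s, t) in ((sp, sp.label) for sp in self.ranked)
                ],
                "retained": [list(l) for l in self.retained],
                "weights": list(map(float, self.weights.weights)),
                "intercept": self.weights.intercept,
                "seed": self.weights.seed,
                "cv_folds": self.weights.cv_folds,
            },
            indent=2,
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


def train_scores(
    records: Sequence[SummaryStatRecord],
    panel: LDPanel,
    tuning_dosages: np.ndarray,
    tuning_keys: Sequence[str],
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> TrainResult:
    """Train a weight table from harmonized records and a tuning cohort."""
    cfg = config or PipelineConfig()
    counts: dict = {}

    @_stage("prefilter")
    def _prefilter():
        kept = prefilter(records, cfg.prefilter_p)
        if not kept:
            raise ValueError(
                f"no records survive the p < {cfg.prefilter_p:g} pre-filter"
            )
        return kept

    kept = _prefilter()
    counts["prefiltered_records"] = len(kept)
    logger.info("prefilter: %d of %d records kept", len(kept), len(records))

    @_stage("clump")
    def _clump():
        return [core.clump(kept, panel, s) for s in cfg.grid()]

    sets = _clump()
    counts["clumped_sets"] = len(sets)
    counts["leads_per_set"] = [len(s.leads) for s in sets]
    logger.info("clump: %d variant sets", len(sets))

    @_stage("effect_matrix")
    def _matrix():
        return core.eb_calibrate(core.build_effect_matrix(sets, kept))

    matrix = _matrix()
    counts["matrix_rows"] = matrix.n_variants
    counts["eb_tau2"] = matrix.eb_params.tau2

    @_stage("candidate_scores")
    def _scores():
        return core.score_individuals(
            tuning_dosages, tuning_keys, matrix, cfg.p_thresholds
        )

    candidates = _scores()
    counts["candidate_scores"] = candidates.shape[1]
    logger.info("scores: %d candidate columns", candidates.shape[1])

    @_stage("rank")
    def _rank():
        return ensemble.rank_scores(candidates, phenotype, covariates)

    ranked = _rank()

    @_stage("prune_correlated")
    def _prune():
        return ensemble.prune_correlated(candidates, ranked, cfg.correlation_prune)

    retained = _prune()
    counts["retained_scores"] = len(retained)

    @_stage("stack")
    def _stack():
        return ensemble.fit_ensemble(
            candidates[retained], phenotype, covariates, cfg.cv_folds, cfg.seed
        )

    weights = _stack()

    @_stage("combine")
    def _combine():
        table = ensemble.combine_weights(matrix, weights)
        # linearity identity: table scoring == weighted candidate-score sum
        lhs = _aligned_dosages(tuning_dosages, tuning_keys, matrix) @ table[
            "weight"
        ].to_numpy()
        rhs = candidates[retained].to_numpy() @ weights.weights
        err = float(np.max(np.abs(lhs - rhs))) if len(lhs) else 0.0
        if err > 1e-8:
            raise ValueError(f"final-weight linearity violated: max |diff| = {err:g}")
        counts["linearity_max_abs_err"] = err
        return table

    table = _combine()
    counts["nonzero_final_weights"] = int((table["weight"] != 0).sum())
    return TrainResult(
        weight_table=table,
        matrix=matrix,
        clumped_sets=sets,
        candidates=candidates,
        ranked=ranked,
        retained=retained,
        weights=weights,
        stage_counts=counts,
    )


def _aligned_dosages(
    dosages: np.ndarray, keys: Sequence[str], matrix: core.EffectSizeMatrix
) -> np.ndarray:
    key_to_col = {k: j for j, k in enumerate(keys)}
    D = np.empty((dosages.shape[0], matrix.n_variants))
    for i, k in enumerate(matrix.variant_keys):
        j = key_to_col.get(k)
        if j is None:
            D[:, i] = 2.0 * matrix.eaf[i]
        else:
            col = dosages[:, j]
            if np.isnan(col).any():
                col = np.where(np.isnan(col), 2.0 * matrix.eaf[i], col)
            D[:, i] = col
    return D


def restrict_common(
    records: Sequence[SummaryStatRecord], maf_min: float = 0.01
) -> list[SummaryStatRecord]:
    """Keep only common variants (MAF >= maf_min): the common-variant-
    restricted baseline arm is trained on this subset."""
    return [r for r in records if r.maf >= maf_min]


def carrier_flags(
    dosages: np.ndarray,
    keys: Sequence[str],
    calls: Sequence[RareVariantCall],
) -> dict[str, np.ndarray]:
    """Carrier indicator per selected rare variant plus pooled risk /
    protective flags (carrier = at least one effect allele)."""
    key_to_col = {k: j for j, k in enumerate(keys)}
    n = dosages.shape[0]
    flags: dict[str, np.ndarray] = {}
    risk = np.zeros(n, dtype=bool)
    protective = np.zeros(n, dtype=bool)
    for call in calls:
        j = key_to_col.get(call.variant_key)
        if j is None:
            continue
        f = np.nan_to_num(dosages[:, j]) > 0.5
        flags[call.variant_key] = f
        if call.direction == "risk":
            risk |= f
        else:
            protective |= f
    flags["risk"] = risk
    flags["protective"] = protective
    return flags


def evaluate_table(
    name: str,
    table: pd.DataFrame,
    cohort_dosages: np.ndarray,
    cohort_keys: Sequence[str],
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    calls: Sequence[RareVariantCall] = (),
    age_at_onset: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    enrichment_flags: Sequence[str] = ("risk",),
) -> evaluate.EvaluationReport:
    """Score a cohort with a weight table and run the evaluation battery."""
    cfg = config or PipelineConfig()
    matched = sum(1 for k in table["variant_key"] if k in set(cohort_keys))
    if len(table) and matched < 0.5 * (table["weight"] != 0).sum():
        raise StageError(
            "score", f"only {matched} of {len(table)} weight variants in cohort"
        )
    raw = ensemble.score_with_table(cohort_dosages, cohort_keys, table)
    flags = carrier_flags(cohort_dosages, cohort_keys, calls) if calls else {}
    return evaluate.evaluate_score(
        name,
        raw,
        phenotype,
        covariates,
        carrier_flags=flags or None,
        age_at_onset=age_at_onset,
        enrichment_spec=cfg.enrichment_spec(),
        enrichment_flags=enrichment_flags,
    )


# ---------------------------------------------------------------------------
# file-based drivers


def run_simulate(
    cfg: PipelineConfig, out_dir=None, overwrite: bool = False, scenario=None
) -> dict:
    """Write scenario fixtures (panel, cohorts, summary stats, relatedness,
    MODY regions) plus a manifest recording the seed. The default scenario is
    used unless another is supplied."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise StageError("simulate", f"{manifest_path} exists (use overwrite)")
    scen = scenario or simulate.default_scenario(cfg.seed)
    panel = simulate.simulate_panel(scen.config)
    panel = apply_mac_filter(panel, cfg.min_mac)
    tuning = simulate.simulate_cohort(
        scen.config, scen.arch, scen.n_tuning, stream=scen.STREAM_TUNING, id_prefix="TUNE"
    )
    test = simulate.simulate_cohort(
        scen.config, scen.arch, scen.n_test, stream=scen.STREAM_TEST, id_prefix="TEST"
    )
    stats_res = simulate.generate_summary_stats(
        panel, scen.arch, scen.n_case_discovery, scen.n_control_discovery,
        seed=cfg.seed,
    )
    files = {
        "sumstats": "sumstats.tsv",
        "panel": "panel_dosages.tsv",
        "tuning": "tuning_cohort.tsv",
        "tuning_phenotypes": "tuning_phenotypes.tsv",
        "test": "test_cohort.tsv",
        "test_phenotypes": "test_phenotypes.tsv",
        "relatedness": "relatedness.tsv",
        "mody_regions": "mody_regions.tsv",
    }
    write_summary_stats(stats_res.records, out / files["sumstats"])
    io.write_dosage_tsv(
        out / files["panel"], panel.dosages,
        panel.variants["variant_key"], panel.individual_ids,
    )
    for cohort, dkey, pkey in (
        (tuning, "tuning", "tuning_phenotypes"),
        (test, "test", "test_phenotypes"),
    ):
        io.write_dosage_tsv(
            out / files[dkey], cohort.dosages, cohort.variant_keys, cohort.ids
        )
        io.write_phenotypes_tsv(out / files[pkey], cohort)
    io.write_relatedness_tsv(
        out / files["relatedness"], tuning.relatedness_pairs + test.relatedness_pairs
    )
    io.write_mody_regions_tsv(
        out / files["mody_regions"], list(scen.rare_rule.mody_regions)
    )
    manifest = {
        "seed": cfg.seed,
        "files": files,
        "n_variants": int(panel.n_variants),
        "n_tuning": tuning.n,
        "n_test": test.n,
        "flagged_sumstats": stats_res.n_flagged,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_cohort(out: Path, files: Mapping[str, str], which: str):
    dosages, keys, ids = io.read_dosage_tsv(out / files[which])
    pheno = io.read_phenotypes_tsv(out / files[f"{which}_phenotypes"])
    cov = pheno[["sex", "age", "bmi", "PC1", "PC2", "PC3", "PC4"]]
    return dosages, keys, ids, pheno["phenotype"].to_numpy(int), cov, pheno


def run_train(cfg: PipelineConfig, fixture_dir=None) -> TrainResult:
    """Train from on-disk fixtures; writes the weight table and report."""
    out = Path(fixture_dir or cfg.out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    files = manifest["files"]
    records, _ = read_summary_stats(out / files["sumstats"])
    panel = io.read_panel_tsv(out / files["panel"])
    panel = apply_mac_filter(panel, cfg.min_mac)
    records = harmonize(records, panel).records
    dosages, keys, ids, phenotype, cov, _ = _load_cohort(out, files, "tuning")
    pairs = io.read_relatedness_tsv(out / files["relatedness"])
    mine = [p for p in pairs if p[0] in set(ids)]
    if mine:
        graph = RelatednessGraph.from_pairs(mine)
        keep_ids = set(prune_related(graph, cfg.pi_hat_max)) | (
            set(ids) - set(graph.nodes)
        )
        keep = np.array([i in keep_ids for i in ids])
        dosages, phenotype, cov = dosages[keep], phenotype[keep], cov.loc[keep]
    result = train_scores(records, panel, dosages, keys, phenotype, cov, cfg)
    ensemble.write_score_file(result.weight_table, out / "final_weights.tsv")
    (out / "ensemble_report.json").write_text(result.report_json())
    return result


def run_evaluate(
    cfg: PipelineConfig,
    weight_paths: Mapping[str, str],
    fixture_dir=None,
) -> dict:
    """Evaluate one or more weight tables on the test cohort, including all
    pairwise DeLong comparisons between tables."""
    out = Path(fixture_dir or cfg.out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    files = manifest["files"]
    records, _ = read_summary_stats(out / files["sumstats"])
    panel = io.read_panel_tsv(out / files["panel"])
    records = harmonize(records, panel).records
    regions = io.read_mody_regions_tsv(out / files["mody_regions"])
    calls = select_rare_variants(records, cfg.rare_rule(regions))
    dosages, keys, ids, phenotype, cov, pheno = _load_cohort(out, files, "test")
    pairs = io.read_relatedness_tsv(out / files["relatedness"])
    mine = [p for p in pairs if p[0] in set(ids)]
    if mine:
        graph = RelatednessGraph.from_pairs(mine)
        keep_ids = set(prune_related(graph, cfg.pi_hat_max)) | (
            set(ids) - set(graph.nodes)
        )
        keep = np.array([i in keep_ids for i in ids])
        dosages, phenotype, cov = dosages[keep], phenotype[keep], cov.loc[keep]
        pheno = pheno.loc[keep]
    onset = pheno["age_at_onset"].to_numpy(float)

    reports: dict[str, evaluate.EvaluationReport] = {}
    probs: dict[str, np.ndarray] = {}
    for name, path in weight_paths.items():
        table = ensemble.read_score_file(path)
        reports[name] = evaluate_table(
            name, table, dosages, keys, phenotype, cov, calls, onset, cfg
        )
        probs[name] = evaluate.standardize_prs(
            ensemble.score_with_table(dosages, keys, table)
        )
    delong = {}
    names = list(weight_paths)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = evaluate.delong_test(probs[a], probs[b], phenotype)
            delong[f"{a}_vs_{b}"] = dataclasses.asdict(res)
    payload = {
        "reports": {k: json.loads(v.to_json()) for k, v in reports.items()},
        "delong": delong,
    }
    (out / "evaluation_report.json").write_text(json.dumps(payload, indent=2))
    for name, rep in reports.items():
        rep.metrics_frame().to_csv(
            out / f"metrics_{name}.tsv", sep="\t", index=False
        )
    return payload
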