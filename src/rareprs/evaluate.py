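"""Carrier-aware evaluation battery for polygenic scores.

Metrics operate on a standardized score (mean 0, SD 1 within the evaluation
population) with case/control phenotype and covariates (sex, age, BMI,
principal components):

- incremental AUC: AUC(case ~ PRS + covariates) - AUC(case ~ covariates);
- paired DeLong test for the difference of two correlated AUCs;
- odds ratio per SD of the PRS from a covariate-adjusted logistic model;
- per-percentile-bin odds ratios against the 40-60th percentile reference;
- carrier statistics: Wilcoxon rank-sum of carrier vs non-carrier PRS and
  the estimated mean carrier odds ratio
  exp(mean(carrier PRS) x log(OR per SD));
- carrier-enrichment resampling: all carriers plus a random multiple of
  non-carriers, iterated, reporting mean and SD of the incremental AUC;
- age-of-onset association: linear model of age at diagnosis on the PRS
  with covariates, in cases only.

AUCs are computed on in-sample fitted probabilities: the evaluation cohort
plays the role of a single held-out test set, so no further splitting is
performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "PERCENTILE_BINS",
    "REFERENCE_BIN",
    "EnrichmentSpec",
    "DelongResult",
    "ORPerSD",
    "CarrierResult",
    "EnrichmentResult",
    "OnsetResult",
    "EvaluationReport",
    "standardize_prs",
    "incremental_auc",
    "delong_test",
    "or_per_sd",
    "percentile_or",
    "carrier_distribution_test",
    "enrichment_sample",
    "age_onset_assoc",
    "evaluate_score",
]

#: percentile bins reported against the 40-60th percentile reference group;
#: the three lowest tail bins overlap by design and are compared separately.
PERCENTILE_BINS: tuple[tuple[float, float], ...] = (
    (0, 2.5),
    (0, 5),
    (0, 10),
    (10, 20),
    (20, 30),
    (30, 40),
    (60, 70),
    (70, 80),
    (80, 90),
    (90, 100),
    (95, 100),
    (97.5, 100),
)
REFERENCE_BIN: tuple[float, float] = (40, 60)


def standardize_prs(raw: np.ndarray) -> np.ndarray:
    """Standardize a raw score to mean 0, SD 1 within the population."""
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    X = covariates.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _fit_probs(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    clf = LogisticRegression(C=1e4, solver="newton-cholesky", max_iter=100)
    clf.fit(X, y)
    return clf.decision_function(X)


def incremental_auc(
    prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
) -> tuple[float, float, float]:
    """(auc_full, auc_cov, iauc): full model adds the PRS to the covariates."""
    y = np.asarray(phenotype, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    Xc = _covariate_design(covariates)
    prs = np.asarray(prs, dtype=float)
    s = prs.std()
    prs_std = (prs - prs.mean()) / s if s > 0 else np.zeros_like(prs)
    auc_cov = float(roc_auc_score(y, _fit_probs(y, Xc)))
    auc_full = float(roc_auc_score(y, _fit_probs(y, np.column_stack([prs_std, Xc]))))
    return auc_full, auc_cov, auc_full - auc_cov


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (cases) and V01 (controls) plus the AUC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01, auc


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    p: float
    z: float
    se_diff: float


def delong_test(
    probs_a: np.ndarray,
    probs_b: np.ndarray,
    phenotype: np.ndarray,
) -> DelongResult:
    """Paired DeLong test for the AUC difference of two scores on the same
    individuals, via placement values; two-sided normal p.

    A degenerate variance (all placements equal) yields p = 1 when the AUCs
    agree and p = 0 otherwise.
    """
    y = np.asarray(phenotype, dtype=int)
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("both scores and the phenotype must align")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    v10a, v01a, auc_a = _delong_placements(a, y)
    v10b, v01b, auc_b = _delong_placements(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        return DelongResult(auc_a, auc_b, 1.0 if diff == 0 else 0.0, 0.0, 0.0)
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(float(auc_a), float(auc_b), p, float(z), float(np.sqrt(var)))


@dataclass(frozen=True)
class ORPerSD:
    or_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool = False


def or_per_sd(
    prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
) -> ORPerSD:
    """Odds ratio per SD of the standardized PRS from logistic regression
    with covariates; Wald 95% CI. Quasi-separation is flagged with an
    unbounded CI instead of raising."""
    y = np.asarray(phenotype, dtype=int)
    prs_std = standardize_prs(prs)
    X = sm.add_constant(np.column_stack([prs_std, _covariate_design(covariates)]))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        if not np.isfinite(se) or se > 50:
            raise np.linalg.LinAlgError
        return ORPerSD(
            or_per_sd=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p=float(fit.pvalues[1]),
        )
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        clf = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
        clf.fit(X[:, 1:], y)
        return ORPerSD(
            or_per_sd=float(np.exp(clf.coef_[0][0])),
            ci_low=0.0,
            ci_high=float("inf"),
            p=float("nan"),
            separation=True,
        )


def percentile_or(
    prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    bins: Sequence[tuple[float, float]] = PERCENTILE_BINS,
    reference: tuple[float, float] = REFERENCE_BIN,
    min_count: int = 10,
) -> pd.DataFrame:
    """Per-bin odds ratios vs the reference percentile group.

    Each listed bin (overlapping tails included) is compared independently
    against the same reference: logistic regression of case status on bin
    membership with covariates, restricted to bin plus reference members.
    Bins with fewer than ``min_count`` individuals are flagged (OR = NaN).
    """
    y = np.asarray(phenotype, dtype=int)
    prs = np.asarray(prs, dtype=float)
    Xc = _covariate_design(covariates)
    # ordinal-rank percentiles: ties broken deterministically by position so
    # every bin holds its nominal share even for a discrete-valued score
    rank_pct = (stats.rankdata(prs, method="ordinal") - 0.5) / len(prs) * 100.0

    def members(interval: tuple[float, float]) -> np.ndarray:
        lo_q, hi_q = interval
        return (rank_pct > lo_q) & (rank_pct <= hi_q)

    ref = members(reference)
    if not ref.any():
        raise ValueError("reference percentile bin is empty")
    rows = []
    for interval in bins:
        if tuple(interval) == tuple(reference):
            rows.append((*interval, 1.0, 1.0, 1.0, float("nan"), int(ref.sum()), False))
            continue
        binm = members(interval)
        sel = binm | ref
        flagged = int(binm.sum()) < min_count
        orv = ci_lo = ci_hi = pv = float("nan")
        if not flagged and len(np.unique(y[sel])) == 2:
            ind = binm[sel].astype(float)
            X = sm.add_constant(
                np.column_stack([ind, Xc[sel]]), has_constant="add"
            )
            try:
                fit = sm.Logit(y[sel], X).fit(disp=0, maxiter=200)
                b, se = float(fit.params[1]), float(fit.bse[1])
                if np.isfinite(se) and se < 50:
                    orv = float(np.exp(b))
                    ci_lo = float(np.exp(b - 1.959963984540054 * se))
                    ci_hi = float(np.exp(b + 1.959963984540054 * se))
                    pv = float(fit.pvalues[1])
                else:
                    flagged = True
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
                flagged = True
        rows.append((*interval, orv, ci_lo, ci_hi, pv, int(binm.sum()), flagged))
    return pd.DataFrame(
        rows,
        columns=["pct_low", "pct_high", "or", "ci_low", "ci_high", "p", "n", "flagged"],
    )


@dataclass(frozen=True)
class CarrierResult:
    wilcoxon_p: float
    mean_carrier_prs: float
    mean_estimated_or: float
    n_carriers: int


def carrier_distribution_test(
    prs_std: np.ndarray,
    carrier_flag: np.ndarray,
    or_per_sd_value: float,
) -> tuple[CarrierResult, np.ndarray]:
    """Wilcoxon rank-sum of carrier vs non-carrier standardized PRS plus the
    estimated mean carrier odds ratio.

    mean estimated OR = exp(mean(carrier PRS) x log(OR per SD)); the
    per-individual estimated ORs exp(PRS_i x log(OR per SD)) are returned for
    the whole population. The rank-sum test is exact below a combined n of
    50 (without ties), else the tie-corrected normal approximation.
    """
    prs_std = np.asarray(prs_std, dtype=float)
    flag = np.asarray(carrier_flag, dtype=bool)
    carriers = prs_std[flag]
    others = prs_std[~flag]
    if carriers.size == 0:
        raise ValueError("no carriers")
    if others.size == 0:
        raise ValueError("no non-carriers")
    n_total = carriers.size + others.size
    has_ties = len(np.unique(prs_std)) < n_total
    method = "exact" if (n_total < 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(carriers, others, alternative="two-sided", method=method)
    log_or = float(np.log(or_per_sd_value))
    mean_prs = float(carriers.mean())
    per_individual = np.exp(prs_std * log_or)
    return (
        CarrierResult(
            wilcoxon_p=float(res.pvalue),
            mean_carrier_prs=mean_prs,
            mean_estimated_or=float(np.exp(mean_prs * log_or)),
            n_carriers=int(carriers.size),
        ),
        per_individual,
    )


@dataclass(frozen=True)
class EnrichmentSpec:
    """Carrier-enrichment resampling: keep all carriers and draw non-carriers
    so the sample totals 4x the carriers (fewer than ``small_carrier_cutoff``
    carriers) or 2x otherwise, over ``iterations`` random draws."""

    small_carrier_cutoff: int = 20
    total_multiplier_small: int = 4
    total_multiplier_large: int = 2
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_multiplier_small < 2 or self.total_multiplier_large < 2:
            raise ValueError("multipliers must be >= 2 so the sample holds all carriers")

    def multiplier(self, n_carriers: int) -> int:
        return (
            self.total_multiplier_small
            if n_carriers < self.small_carrier_cutoff
            else self.total_multiplier_large
        )


@dataclass(frozen=True)
class EnrichmentResult:
    mean_iauc: float
    sd_iauc: float
    iaucs: tuple[float, ...]
    sample_size: int


def enrichment_sample(
    prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    carrier_flag: np.ndarray,
    spec: EnrichmentSpec,
) -> EnrichmentResult:
    """Mean and SD of incremental AUC across carrier-enriched subsamples."""
    flag = np.asarray(carrier_flag, dtype=bool)
    n_car = int(flag.sum())
    if n_car == 0:
        raise ValueError("no carriers to enrich")
    mult = spec.multiplier(n_car)
    n_non = (mult - 1) * n_car
    non_idx = np.flatnonzero(~flag)
    if non_idx.size < n_non:
        raise ValueError(
            f"need {n_non} non-carriers but only {non_idx.size} are available"
        )
    rng = np.random.default_rng(spec.seed)
    car_idx = np.flatnonzero(flag)
    iaucs = []
    prs = np.asarray(prs, dtype=float)
    y = np.asarray(phenotype, dtype=int)
    for _ in range(spec.iterations):
        draw = rng.choice(non_idx, size=n_non, replace=False)
        sel = np.concatenate([car_idx, draw])
        _, _, iauc = incremental_auc(prs[sel], y[sel], covariates.iloc[sel])
        iaucs.append(iauc)
    arr = np.array(iaucs)
    return EnrichmentResult(
        mean_iauc=float(arr.mean()),
        sd_iauc=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        iaucs=tuple(map(float, arr)),
        sample_size=mult * n_car,
    )


@dataclass(frozen=True)
class OnsetResult:
    beta_per_sd: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def age_onset_assoc(
    prs_std: np.ndarray,
    age_at_onset: np.ndarray,
    covariates: pd.DataFrame,
    min_cases: int = 30,
) -> OnsetResult:
    """Linear association of age at diagnosis with the standardized PRS among
    cases (years per PRS SD), adjusting for covariates."""
    onset = np.asarray(age_at_onset, dtype=float)
    ok = np.isfinite(onset)
    if ok.sum() < min_cases:
        raise ValueError(
            f"need at least {min_cases} cases with age at onset, have {int(ok.sum())}"
        )
    X = sm.add_constant(
        np.column_stack(
            [np.asarray(prs_std, dtype=float)[ok], _covariate_design(covariates)[ok]]
        )
    )
    fit = sm.OLS(onset[ok], X).fit()
    b, se = float(fit.params[1]), float(fit.bse[1])
    return OnsetResult(
        beta_per_sd=b,
        ci_low=b - 1.959963984540054 * se,
        ci_high=b + 1.959963984540054 * se,
        p=float(fit.pvalues[1]),
        n=int(ok.sum()),
    )


@dataclass
class EvaluationReport:
    """Evaluation of one score on one cohort; JSON/TSV serializable."""

    score_name: str
    auc_full: float
    auc_cov: float
    iauc: float
    or_per_sd: ORPerSD
    percentile_or: pd.DataFrame
    carriers: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    onset: OnsetResult | None = None

    def to_json(self) -> str:
        payload = {
            "score_name": self.score_name,
            "auc_full": self.auc_full,
            "auc_cov": self.auc_cov,
            "iauc": self.iauc,
            "or_per_sd": asdict(self.or_per_sd),
            "percentile_or": self.percentile_or.to_dict(orient="records"),
            "carriers": {k: asdict(v) for k, v in self.carriers.items()},
            "enrichment": {
                k: {
                    "mean_iauc": v.mean_iauc,
                    "sd_iauc": v.sd_iauc,
                    "sample_size": v.sample_size,
                }
                for k, v in self.enrichment.items()
            },
            "onset": asdict(self.onset) if self.onset is not None else None,
        }
        return json.dumps(payload, indent=2)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            ("auc_full", self.auc_full),
            ("auc_cov", self.auc_cov),
            ("iauc", self.iauc),
            ("or_per_sd", self.or_per_sd.or_per_sd),
        ]
        for k, v in self.carriers.items():
            rows.append((f"carrier_{k}_mean_estimated_or", v.mean_estimated_or))
            rows.append((f"carrier_{k}_wilcoxon_p", v.wilcoxon_p))
        for k, v in self.enrichment.items():
            rows.append((f"enrichment_{k}_mean_iauc", v.mean_iauc))
        if self.onset is not None:
            rows.append(("onset_beta_per_sd", self.onset.beta_per_sd))
        return pd.DataFrame(rows, columns=["metric", "value"])


def evaluate_score(
    score_name: str,
    raw_prs: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    carrier_flags: Mapping[str, np.ndarray] | None = None,
    age_at_onset: np.ndarray | None = None,
    enrichment_spec: EnrichmentSpec | None = None,
    enrichment_flags: Sequence[str] = (),
) -> EvaluationReport:
    """Run the full battery for one score on one cohort."""
    prs_std = standardize_prs(raw_prs)
    auc_full, auc_cov, iauc = incremental_auc(prs_std, phenotype, covariates)
    orsd = or_per_sd(prs_std, phenotype, covariates)
    pct = percentile_or(prs_std, phenotype, covariates)
    report = EvaluationReport(
        score_name=score_name,
        auc_full=auc_full,
        auc_cov=auc_cov,
        iauc=iauc,
        or_per_sd=orsd,
        percentile_or=pct,
    )
    if carrier_flags:
        for name, flag in carrier_flags.items():
            if np.asarray(flag, dtype=bool).any():
                res, _ = carrier_distribution_test(prs_std, flag, orsd.or_per_sd)
                report.carriers[name] = res
        if enrichment_spec is not None:
            for name in enrichment_flags:
                flag = carrier_flags.get(name)
                if flag is None or not np.asarray(flag, dtype=bool).any():
                    continue
                report.enrichment[name] = enrichment_sample(
                    prs_std, phenotype, covariates, flag, enrichment_spec
                )
    if age_at_onset is not None and np.isfinite(np.asarray(age_at_onset, float)).sum() >= 30:
        report.onset = age_onset_assoc(prs_std, age_at_onset, covariates)
    return report
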