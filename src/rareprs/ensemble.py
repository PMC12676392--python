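"""Ensemble combination of candidate scores into one distributable weight table.

Candidate scores are ranked by the AUC of a logistic model of case status on
score plus covariates in the tuning cohort; scores correlating more than
0.98 with the top performer are near-duplicates and are excluded. The
retained scores are stacked with cross-validated elastic-net logistic
regression (covariates residualized out of the score columns beforehand, so
covariate signal cannot leak into variant weights), and the fitted
combination collapses algebraically onto per-variant weights:

    final_weight(v) = beta_EB(v) * sum_k w_k * [v in support of score k]

so scoring a cohort with the weight table reproduces the weighted sum of
candidate scores exactly, and the table alone is distributable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import EffectSizeMatrix
from .sumstats import parse_variant_key

__all__ = [
    "ScorePerformance",
    "EnsembleWeights",
    "rank_scores",
    "prune_correlated",
    "fit_ensemble",
    "combine_weights",
    "write_score_file",
    "read_score_file",
    "score_with_table",
]


@dataclass(frozen=True)
class ScorePerformance:
    label: tuple
    auc: float


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = covariates.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def rank_scores(
    candidates: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
) -> list[ScorePerformance]:
    """Rank candidate scores by AUC of logistic(case ~ score + covariates).

    Returns performances sorted descending by AUC (ties keep column order).
    AUC is rank-based, so affine rescaling of a score column cannot change
    its rank.
    """
    y = np.asarray(phenotype, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both cases and controls")
    Xc = _design(covariates)
    perfs: list[ScorePerformance] = []
    for label in candidates.columns:
        s = candidates[label].to_numpy(dtype=float)
        sd = s.std()
        s_std = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        X = np.column_stack([s_std, Xc])
        clf = LogisticRegression(C=1e4, solver="newton-cholesky", max_iter=100)
        clf.fit(X, y)
        auc = float(roc_auc_score(y, clf.decision_function(X)))
        perfs.append(ScorePerformance(label=tuple(label), auc=auc))
    perfs.sort(key=lambda sp: -sp.auc)
    return perfs


def prune_correlated(
    candidates: pd.DataFrame,
    ranked: Sequence[ScorePerformance],
    r_max: float = 0.98,
) -> list[tuple]:
    """Drop scores whose Pearson correlation with the top-ranked score
    strictly exceeds ``r_max``; the top score is always retained.

    An undefined correlation (constant column) never triggers exclusion.
    """
    if not ranked:
        raise ValueError("ranked score list is empty")
    top = ranked[0].label
    top_col = candidates[top].to_numpy(dtype=float)
    retained: list[tuple] = [top]
    for sp in ranked[1:]:
        col = candidates[sp.label].to_numpy(dtype=float)
        if top_col.std() == 0 or col.std() == 0:
            retained.append(sp.label)
            continue
        r = float(np.corrcoef(top_col, col)[0, 1])
        if not abs(r) > r_max:
            retained.append(sp.label)
    return retained


@dataclass(frozen=True)
class EnsembleWeights:
    """Fitted stacking weights over the retained candidate scores."""

    labels: tuple[tuple, ...]
    weights: np.ndarray
    intercept: float
    seed: int
    cv_folds: int

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.weights):
            raise ValueError("one weight per retained score required")

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": [[s, t] for s, t in self.labels],
                "weights": list(map(float, self.weights)),
                "intercept": self.intercept,
                "seed": self.seed,
                "cv_folds": self.cv_folds,
            },
            indent=2,
        )


def _residualize(S: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Remove the least-squares covariate projection from each score column."""
    X = np.column_stack([np.ones(len(covariates)), _design(covariates)])
    coef, *_ = np.linalg.lstsq(X, S, rcond=None)
    return S - X @ coef


def fit_ensemble(
    candidates: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: pd.DataFrame,
    cv_folds: int = 5,
    seed: int = 0,
) -> EnsembleWeights:
    """Cross-validated elastic-net logistic stacking of the retained scores.

    Score columns are residualized against the covariates and standardized;
    fitted coefficients are mapped back to the raw score scale. Constant
    columns receive weight 0. Deterministic given ``seed``.
    """
    if candidates.shape[1] == 0:
        raise ValueError("no retained scores to stack")
    y = np.asarray(phenotype, dtype=int)
    S = candidates.to_numpy(dtype=float)
    sd_raw = S.std(axis=0)
    if not (sd_raw > 0).any():
        raise ValueError("all retained score columns are constant")
    R = _residualize(S, covariates)
    sd = R.std(axis=0)
    live = sd > 1e-12
    Z = np.zeros_like(R)
    Z[:, live] = (R[:, live] - R[:, live].mean(axis=0)) / sd[live]
    # exactly identical standardized columns (same variant support after
    # thresholding) act as one predictor: fit on unique columns and give the
    # shared coefficient to the first representative
    live_idx = np.flatnonzero(live)
    _, first, inv = np.unique(
        np.round(Z[:, live_idx], 12), axis=1, return_index=True, return_inverse=True
    )
    rep_idx = live_idx[first]
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-2, 1, 4),
        cv=cv,
        l1_ratios=[0.5],
        solver="saga",
        scoring="neg_log_loss",
        max_iter=2000,
        tol=1e-3,
        random_state=seed,
        n_jobs=1,
        use_legacy_attributes=False,
    )
    clf.fit(Z[:, rep_idx], y)
    weights = np.zeros(S.shape[1])
    weights[rep_idx] = clf.coef_.ravel() / sd[rep_idx]
    return EnsembleWeights(
        labels=tuple(tuple(c) for c in candidates.columns),
        weights=weights,
        intercept=float(clf.intercept_[0]),
        seed=seed,
        cv_folds=cv_folds,
    )


def combine_weights(
    matrix: EffectSizeMatrix,
    weights: EnsembleWeights,
) -> pd.DataFrame:
    """Collapse stacking weights onto per-variant final weights.

    Returns the distributable weight table (variant_key, effect_allele,
    weight). The identity  dosages @ weight == sum_k w_k * score_k  holds
    exactly up to float error for any cohort.
    """
    if matrix.beta_eb is None:
        raise ValueError("matrix must be EB-calibrated")
    total = np.zeros(matrix.n_variants)
    for (s_idx, thr), w in zip(weights.labels, weights.weights):
        if not 0 <= s_idx < len(matrix.settings):
            raise ValueError(f"weight references unknown setting index {s_idx}")
        support = matrix.lead_mask[:, s_idx] & (matrix.p < thr)
        total += w * support
    final = matrix.beta_eb * total
    alts = [parse_variant_key(k)[3] for k in matrix.variant_keys]
    return pd.DataFrame(
        {
            "variant_key": list(matrix.variant_keys),
            "effect_allele": alts,
            "weight": final,
        }
    )


def write_score_file(table: pd.DataFrame, path) -> None:
    """Serialize the weight table as TSV with >= 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("variant_key\teffect_allele\tweight\n")
        for _, row in table.iterrows():
            fh.write(f"{row['variant_key']}\t{row['effect_allele']}\t{row['weight']:.12g}\n")


def read_score_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "effect_allele": str})
    df["weight"] = df["weight"].astype(float)
    return df


def score_with_table(
    dosages: np.ndarray,
    dosage_keys: Sequence[str],
    table: pd.DataFrame,
    eaf: Sequence[float] | None = None,
) -> np.ndarray:
    """Score a cohort with a final weight table (missing variants impute to a
    constant when ``eaf`` per table row is given, else 0 contribution)."""
    dosages = np.asarray(dosages, dtype=float)
    key_to_col = {k: j for j, k in enumerate(dosage_keys)}
    out = np.zeros(dosages.shape[0])
    for i, (_, row) in enumerate(table.iterrows()):
        w = row["weight"]
        if w == 0.0:
            continue
        j = key_to_col.get(row["variant_key"])
        if j is None:
            fill = 2.0 * eaf[i] if eaf is not None else 0.0
            out += w * fill
            continue
        col = dosages[:, j]
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        out += w * col
    return out
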