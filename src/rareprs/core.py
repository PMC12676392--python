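"""Score-construction engine: clumping grid, effect-size matrix, empirical-Bayes
shrinkage and candidate-score computation.

Clumping and thresholding over a grid of LD settings produces multiple
candidate variant sets from one set of summary statistics. Each clump
setting pairs an r-squared threshold with a base genomic window; the
effective window is the base window divided by the r-squared threshold, so
looser LD thresholds search wider windows. The default grid of 6 r-squared
thresholds x 2 base windows yields 12 variant sets; combined with the
9-value p-value threshold grid these define 108 candidate scores per
individual.

The effect-size matrix places each lead variant's estimated log-odds in the
columns of the settings where it leads and 0 elsewhere — a variant clumped
away under one setting contributes nothing to that setting's score.

Empirical-Bayes calibration shrinks each estimated log-odds toward zero with
a normal-normal method-of-moments factor tau2/(tau2 + se^2), where tau2 is
the excess of the observed effect variance over the mean squared standard
error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ldpanel import LDPanel, r2_one_vs_many
from .sumstats import SummaryStatRecord, parse_variant_key

__all__ = [
    "R2_THRESHOLDS",
    "BASE_WINDOWS_KB",
    "P_THRESHOLDS",
    "ClumpSetting",
    "ClumpedVariantSet",
    "EffectSizeMatrix",
    "EBParams",
    "default_grid",
    "effective_window",
    "clump",
    "clump_grid",
    "build_effect_matrix",
    "eb_calibrate",
    "score_individuals",
]

#: r-squared thresholds of the clumping grid
R2_THRESHOLDS: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.5, 0.8)
#: base clumping windows in kilobases
BASE_WINDOWS_KB: tuple[float, ...] = (50.0, 100.0)
#: p-value threshold grid: the eight half-decade values from 5e-11 to 5e-4
#: plus 5e-3, giving nine thresholds and 12 x 9 = 108 candidate scores.
#: Configurable wherever it is consumed.
P_THRESHOLDS: tuple[float, ...] = (
    5e-11,
    5e-10,
    5e-9,
    5e-8,
    5e-7,
    5e-6,
    5e-5,
    5e-4,
    5e-3,
)


@dataclass(frozen=True)
class ClumpSetting:
    """One cell of the clumping grid."""

    r2_threshold: float
    base_window_kb: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.base_window_kb <= 0:
            raise ValueError("base_window_kb must be positive")

    @property
    def effective_window_kb(self) -> float:
        return self.base_window_kb / self.r2_threshold

    @property
    def label(self) -> str:
        return f"r2_{self.r2_threshold:g}_w{self.base_window_kb:g}kb"


def default_grid(
    r2_thresholds: Sequence[float] = R2_THRESHOLDS,
    base_windows_kb: Sequence[float] = BASE_WINDOWS_KB,
) -> tuple[ClumpSetting, ...]:
    """The clumping grid, windows-major then ascending r-squared."""
    return tuple(
        ClumpSetting(r2, w) for w in base_windows_kb for r2 in r2_thresholds
    )


def effective_window(setting: ClumpSetting) -> float:
    """Effective clumping window in kb: base window / r-squared threshold."""
    return setting.effective_window_kb


@dataclass(frozen=True)
class ClumpedVariantSet:
    """Lead variants of one clump setting, in ascending p-value order."""

    setting: ClumpSetting
    leads: tuple[str, ...]


def clump(
    records: Sequence[SummaryStatRecord],
    panel: LDPanel,
    setting: ClumpSetting,
) -> ClumpedVariantSet:
    """Greedy clumping: repeatedly promote the smallest-p unclaimed variant to
    lead and claim all unclaimed variants within the effective window whose
    r-squared with the lead meets the threshold.

    Ties at equal p break on smaller genomic position, then lexicographic
    variant key, so the result does not depend on record order. Undefined
    r-squared never claims a variant.
    """
    if not records:
        return ClumpedVariantSet(setting=setting, leads=())
    keys = [r.variant_key for r in records]
    idx = np.array([panel.index_of(k) for k in keys])
    p = np.array([r.p for r in records])
    chrom = np.array([panel.variants["chrom"].iloc[i] for i in idx])
    pos = np.array([panel.variants["pos"].iloc[i] for i in idx])

    order = sorted(
        range(len(records)), key=lambda i: (p[i], chrom[i], pos[i], keys[i])
    )
    # per-chromosome position-sorted candidate lists for window queries
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(chrom):
        members = np.flatnonzero(chrom == c)
        by_chrom[c] = members[np.argsort(pos[members], kind="stable")]

    span = setting.effective_window_kb * 1000.0
    claimed = np.zeros(len(records), dtype=bool)
    leads: list[str] = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        leads.append(keys[i])
        members = by_chrom[chrom[i]]
        mpos = pos[members]
        lo = np.searchsorted(mpos, pos[i] - span, side="left")
        hi = np.searchsorted(mpos, pos[i] + span, side="right")
        window = members[lo:hi]
        window = window[~claimed[window]]
        if window.size == 0:
            continue
        r2 = r2_one_vs_many(panel, idx[i], idx[window])
        hit = window[np.nan_to_num(r2, nan=-1.0) >= setting.r2_threshold]
        claimed[hit] = True
    return ClumpedVariantSet(setting=setting, leads=tuple(leads))


def clump_grid(
    records: Sequence[SummaryStatRecord],
    panel: LDPanel,
    settings: Sequence[ClumpSetting] | None = None,
) -> list[ClumpedVariantSet]:
    if settings is None:
        settings = default_grid()
    return [clump(records, panel, s) for s in settings]


@dataclass(frozen=True)
class EBParams:
    """Prior variance of true log-odds under the normal-normal model."""

    tau2: float

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")


@dataclass(frozen=True)
class EffectSizeMatrix:
    """Union of clump leads x clump settings.

    ``beta`` holds the raw estimated log-odds per row variant; ``lead_mask``
    marks the settings where the variant is a lead (entry beta, else 0).
    ``beta_eb`` is filled by :func:`eb_calibrate`.
    """

    variant_keys: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    eaf: np.ndarray
    lead_mask: np.ndarray  # (n_variants, n_settings) bool
    settings: tuple[ClumpSetting, ...]
    beta_eb: np.ndarray | None = None
    eb_params: EBParams | None = None

    def __post_init__(self) -> None:
        if self.lead_mask.shape != (len(self.variant_keys), len(self.settings)):
            raise ValueError("lead_mask shape mismatch")
        if len(self.variant_keys) and not self.lead_mask.any(axis=1).all():
            raise ValueError("every matrix row must lead in at least one setting")

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def matrix(self, shrunk: bool = False) -> np.ndarray:
        """Dense variants x settings matrix of effect sizes (0 off-support)."""
        b = self.beta_eb if shrunk else self.beta
        if b is None:
            raise ValueError("matrix not yet calibrated; run eb_calibrate first")
        return b[:, None] * self.lead_mask

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "variant_key": list(self.variant_keys),
            "se": self.se,
            "p": self.p,
            "eaf": self.eaf,
        }
        dense = self.beta[:, None] * self.lead_mask
        for j, s in enumerate(self.settings):
            cols[f"beta_{s.label}"] = dense[:, j]
        if self.beta_eb is not None:
            cols["beta_eb"] = self.beta_eb
        return pd.DataFrame(cols)


def build_effect_matrix(
    sets: Sequence[ClumpedVariantSet],
    records: Sequence[SummaryStatRecord],
) -> EffectSizeMatrix:
    """Assemble the effect-size matrix from the full grid of clumped sets.

    Rows are the union of leads (genome order); entry (v, s) is the record
    beta when v leads under setting s, else 0. A lead absent from the records
    is an internal inconsistency and a hard error.
    """
    by_key = {r.variant_key: r for r in records}
    union: set[str] = set()
    for s in sets:
        union.update(s.leads)
    missing = sorted(k for k in union if k not in by_key)
    if missing:
        raise ValueError(f"clump leads missing from records: {missing[:5]}")

    def sort_key(k: str):
        chrom, pos, ref, alt = parse_variant_key(k)
        return (chrom, pos, ref, alt)

    keys = tuple(sorted(union, key=sort_key))
    key_idx = {k: i for i, k in enumerate(keys)}
    mask = np.zeros((len(keys), len(sets)), dtype=bool)
    for j, s in enumerate(sets):
        for k in s.leads:
            mask[key_idx[k], j] = True
    beta = np.array([by_key[k].beta for k in keys])
    se = np.array([by_key[k].se for k in keys])
    p = np.array([by_key[k].p for k in keys])
    eaf = np.array([by_key[k].eaf for k in keys])
    m = EffectSizeMatrix(
        variant_keys=keys,
        beta=beta,
        se=se,
        p=p,
        eaf=eaf,
        lead_mask=mask,
        settings=tuple(s.setting for s in sets),
    )
    # column support equals each setting's lead set by construction
    assert all(
        mask[:, j].sum() == len(s.leads) for j, s in enumerate(sets)
    )
    return m


def eb_calibrate(matrix: EffectSizeMatrix) -> EffectSizeMatrix:
    """Normal-normal method-of-moments shrinkage of the row effect sizes.

    tau2 = max(0, var(beta) - mean(se^2)) over the matrix rows; each beta is
    scaled by tau2 / (tau2 + se^2). In the limit se -> 0 the estimate is
    untouched; when the observed effect variance is fully explained by
    sampling noise (tau2 = 0) every effect shrinks to 0.
    """
    valid = np.isfinite(matrix.se) & (matrix.se > 0) & np.isfinite(matrix.beta)
    if valid.sum() < 2:
        raise ValueError("eb_calibrate needs at least 2 variants with valid se")
    b = matrix.beta[valid]
    tau2 = max(0.0, float(np.var(b, ddof=1)) - float(np.mean(matrix.se[valid] ** 2)))
    shrink = tau2 / (tau2 + matrix.se**2)
    beta_eb = np.where(valid, matrix.beta * shrink, 0.0)
    return replace(matrix, beta_eb=beta_eb, eb_params=EBParams(tau2=tau2))


def eb_shrink(beta: np.ndarray, se: np.ndarray) -> tuple[float, np.ndarray]:
    """Stand-alone shrinkage on (beta, se) vectors; returns (tau2, shrunk)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if beta.size < 2:
        raise ValueError("need at least 2 variants")
    tau2 = max(0.0, float(np.var(beta, ddof=1)) - float(np.mean(se**2)))
    return tau2, beta * (tau2 / (tau2 + se**2))


def score_individuals(
    dosages: np.ndarray,
    dosage_keys: Sequence[str],
    matrix: EffectSizeMatrix,
    p_thresholds: Sequence[float] = P_THRESHOLDS,
) -> pd.DataFrame:
    """Compute the candidate-score matrix: one column per (setting, threshold).

    score(i; s, t) = sum_v dosage(i, v) * beta_eb(v) * [v leads in s] * [p_v < t].

    Missing dosage entries are mean-imputed at 2 x EAF; matrix variants
    absent from the dosage columns contribute their imputed constant. A
    complete lack of overlap is a hard error.
    """
    if matrix.beta_eb is None:
        raise ValueError("matrix must be EB-calibrated before scoring")
    dosages = np.asarray(dosages, dtype=float)
    key_to_col = {k: j for j, k in enumerate(dosage_keys)}
    n = dosages.shape[0]
    overlap = sum(1 for k in matrix.variant_keys if k in key_to_col)
    if matrix.n_variants and overlap == 0:
        raise ValueError("no overlap between dosage variants and matrix rows")

    # assemble an n x m dosage slab aligned to matrix rows, imputing as we go
    D = np.empty((n, matrix.n_variants))
    for i, k in enumerate(matrix.variant_keys):
        j = key_to_col.get(k)
        fill = 2.0 * matrix.eaf[i]
        if j is None:
            D[:, i] = fill
        else:
            col = dosages[:, j]
            if np.isnan(col).any():
                col = np.where(np.isnan(col), fill, col)
            D[:, i] = col

    labels = []
    cols = []
    for s_idx in range(len(matrix.settings)):
        w_s = matrix.beta_eb * matrix.lead_mask[:, s_idx]
        for t in p_thresholds:
            w = w_s * (matrix.p < t)
            cols.append(D @ w)
            labels.append((s_idx, t))
    out = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n, 0)),
        columns=pd.MultiIndex.from_tuples(labels, names=["setting", "p_threshold"]),
    )
    return out
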