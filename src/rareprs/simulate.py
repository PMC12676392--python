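"""Synthetic genotype / phenotype / summary-statistic generator.

The generator provides every input the score-construction and evaluation
stages need, with the statistical structure the pipeline assumes:

- LD-block genotypes: haplotypes arise from latent Gaussians with AR(1)
  correlation ``block_rho`` within independent blocks, thresholded at the
  per-variant, per-subpopulation allele frequency. Summing two haplotypes
  per individual yields Hardy-Weinberg-consistent dosages with tunable
  r-squared decay along each block.
- Allele-frequency spectrum: alt frequencies are drawn log-uniformly over
  ``maf_range`` (reaching rare frequencies), with Balding-Nichols drift
  across subpopulations controlled by ``fst_like_divergence``. Specific
  variants can be pinned to chosen (per-subpopulation) frequencies, which is
  how the large-effect rare variants of the default scenario are placed.
- Phenotypes: a liability threshold model. Liability is the standardized
  log-odds-weighted genetic score scaled to ``liability_h2``, plus fixed
  covariate effects (sex, age, BMI) and Gaussian noise; an individual is a
  case when liability exceeds the standard-normal quantile of
  1 - prevalence. Realized carrier odds ratios under this model are
  approximate transforms of the nominal log-odds (see docs/methods.md) and
  are checked against a brute-force logistic fit in the tests.
- Summary statistics: analytic mode draws beta_hat ~ Normal(beta, se^2) with
  the closed-form score-test standard error
  se = 1 / sqrt(2 p (1-p) N phi (1-phi)), phi the case fraction; cohort mode
  runs an actual per-variant score test on a simulated discovery cohort.

All outputs are pure functions of (config, seed): the same configuration
reproduces bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ldpanel import LDPanel, panel_from_dosages
from .sumstats import RareVariantRule, SummaryStatRecord

__all__ = [
    "SimulationConfig",
    "RareEffect",
    "CausalArchitecture",
    "SimulatedCohort",
    "Scenario",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "generate_summary_stats",
    "default_scenario",
    "variant_keys",
]

# fixed covariate effects on the liability scale (standardized covariates)
_C_SEX = 0.10
_C_AGE = 0.20
_C_BMI = 0.25
_COV_VAR = _C_SEX**2 + _C_AGE**2 + _C_BMI**2

# internal stream labels: panel, tuning, test, sumstats, frequencies, betas
_STREAM_FREQ = 11


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for the LD-structured genotype panel."""

    n_variants: int = 900
    n_blocks: int = 45
    block_rho: float = 0.9
    maf_range: tuple[float, float] = (1e-4, 0.5)
    n_subpops: int = 2
    fst_like_divergence: float = 0.02
    seed: int = 0
    n_ref_individuals: int = 800
    pos_step_bp: int = 25_000
    block_gap_bp: int = 500_000
    related_fraction: float = 0.01
    freq_overrides: Mapping[int, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if not 1 <= self.n_blocks <= self.n_variants:
            raise ValueError("n_blocks must lie in [1, n_variants]")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.fst_like_divergence < 0:
            raise ValueError("fst_like_divergence must be nonnegative")

    def block_sizes(self) -> np.ndarray:
        """Block sizes summing exactly to n_variants (remainder spread first)."""
        base = self.n_variants // self.n_blocks
        sizes = np.full(self.n_blocks, base, dtype=int)
        sizes[: self.n_variants - base * self.n_blocks] += 1
        return sizes


def _positions(config: SimulationConfig) -> np.ndarray:
    sizes = config.block_sizes()
    pos = np.empty(config.n_variants, dtype=int)
    cursor = 1
    k = 0
    for size in sizes:
        for j in range(size):
            pos[k] = cursor + j * config.pos_step_bp
            k += 1
        cursor += size * config.pos_step_bp + config.block_gap_bp
    return pos


def variant_keys(config: SimulationConfig) -> list[str]:
    """Deterministic chrom:pos:ref:alt keys (all chromosome 1, A>G)."""
    return [f"1:{p}:A:G" for p in _positions(config)]


def _allele_frequencies(config: SimulationConfig) -> np.ndarray:
    """Per-subpopulation alt-allele frequencies, shape (n_subpops, n_variants).

    Deterministic given the config seed so that the reference panel and every
    cohort share the same generative frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_FREQ]))
    lo, hi = config.maf_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_variants))
    F = config.fst_like_divergence
    if F > 0 and config.n_subpops > 1:
        a = base * (1 - F) / F
        b = (1 - base) * (1 - F) / F
        freqs = rng.beta(a, b, size=(config.n_subpops, config.n_variants))
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    else:
        freqs = np.tile(base, (config.n_subpops, 1))
    for idx, override in config.freq_overrides.items():
        vals = np.atleast_1d(np.asarray(override, dtype=float))
        if vals.size == 1:
            vals = np.repeat(vals, config.n_subpops)
        if vals.size != config.n_subpops:
            raise ValueError("freq override must be scalar or per-subpopulation")
        freqs[:, idx] = vals
    return freqs


def _subpop_labels(config: SimulationConfig, n: int) -> np.ndarray:
    return np.arange(n) % config.n_subpops


class _Genotypes(NamedTuple):
    dosages: np.ndarray  # n x m float
    haplotypes: np.ndarray  # 2n x m bool
    subpop: np.ndarray  # n int


def simulate_genotypes(
    config: SimulationConfig, n_individuals: int, rng: np.random.Generator
) -> _Genotypes:
    """Draw dosages for ``n_individuals`` from the block-AR(1) threshold model."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    freqs = _allele_frequencies(config)
    subpop = _subpop_labels(config, n_individuals)
    hap_subpop = np.repeat(subpop, 2)
    thresholds = stats.norm.ppf(freqs)  # (S, m)
    n_hap = 2 * n_individuals
    haps = np.empty((n_hap, config.n_variants), dtype=bool)
    sizes = config.block_sizes()
    start = 0
    rho = config.block_rho
    for size in sizes:
        cols = slice(start, start + size)
        Z = rng.standard_normal((n_hap, size))
        if rho > 0 and size > 1:
            corr = rho ** np.abs(np.subtract.outer(np.arange(size), np.arange(size)))
            L = np.linalg.cholesky(corr)
            Z = Z @ L.T
        haps[:, cols] = Z < thresholds[:, cols][hap_subpop]
        start += size
    dosages = (haps[0::2].astype(np.float64) + haps[1::2]).astype(np.float64)
    return _Genotypes(dosages=dosages, haplotypes=haps, subpop=subpop)


def simulate_panel(config: SimulationConfig) -> LDPanel:
    """Simulate the LD reference panel (``n_ref_individuals`` individuals)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    geno = simulate_genotypes(config, config.n_ref_individuals, rng)
    return panel_from_dosages(geno.dosages, variant_keys(config))


@dataclass(frozen=True)
class RareEffect:
    """A large-effect rare variant: log-odds plus its gene-class tag."""

    beta: float
    gene_class: str  # "mody" | "non_mody"

    def __post_init__(self) -> None:
        if abs(self.beta) < 0.3:
            raise ValueError("rare effects must have |log-odds| >= 0.3")
        if self.gene_class not in ("mody", "non_mody"):
            raise ValueError("gene_class must be 'mody' or 'non_mody'")


@dataclass(frozen=True)
class CausalArchitecture:
    """True effect sizes underlying the liability model.

    ``common_effects`` maps variant keys to log-odds for the polygenic
    background (many small effects); ``rare_effects`` holds the large-effect
    rare variants (target MAF < 0.03), a subset of which may be
    population-specific (frequency differs across subpopulations).
    """

    common_effects: Mapping[str, float] = field(default_factory=dict)
    rare_effects: Mapping[str, RareEffect] = field(default_factory=dict)
    population_specific: frozenset[str] = frozenset()
    liability_h2: float = 0.5
    prevalence: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.liability_h2 <= 1.0:
            raise ValueError("liability_h2 must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        unknown = set(self.population_specific) - set(self.rare_effects)
        if unknown:
            raise ValueError("population_specific keys must be rare_effects keys")

    def beta_vector(self, keys: Sequence[str]) -> np.ndarray:
        lookup = dict(self.common_effects)
        lookup.update({k: re.beta for k, re in self.rare_effects.items()})
        missing = set(lookup) - set(keys)
        if missing:
            raise ValueError(f"architecture variants absent from panel: {sorted(missing)[:5]}")
        return np.array([lookup.get(k, 0.0) for k in keys])


@dataclass
class SimulatedCohort:
    """Individuals with dosages, phenotype, covariates and relatedness."""

    ids: list[str]
    variant_keys: list[str]
    dosages: np.ndarray
    phenotype: np.ndarray  # 0/1
    covariates: pd.DataFrame  # sex, age, bmi, PC1..PC4
    subpop: np.ndarray
    liability: np.ndarray
    genetic_score: np.ndarray  # standardized true genetic liability component
    age_at_onset: np.ndarray  # NaN for controls
    relatedness_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)


def _covariates(
    rng: np.random.Generator, n: int, subpop: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    sex = rng.integers(0, 2, size=n)
    age = np.clip(rng.normal(55, 8, size=n), 30, 80)
    bmi = np.clip(rng.normal(28, 5, size=n), 16, 55)
    sp_centered = subpop - subpop.mean()
    sp_sd = sp_centered.std()
    pc1 = (sp_centered / sp_sd if sp_sd > 0 else sp_centered) + rng.normal(0, 0.3, n)
    pcs = rng.normal(0, 1, size=(n, 3))
    cov = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "PC1": pc1,
            "PC2": pcs[:, 0],
            "PC3": pcs[:, 1],
            "PC4": pcs[:, 2],
        }
    )
    # liability contribution on nominal standardized scales
    z_age = (age - 55.0) / 8.0
    z_bmi = (bmi - 28.0) / 5.0
    z_sex = (sex - 0.5) / 0.5
    contrib = _C_SEX * z_sex + _C_AGE * z_age + _C_BMI * z_bmi
    return cov, contrib


def simulate_phenotypes(
    dosages: np.ndarray,
    keys: Sequence[str],
    arch: CausalArchitecture,
    config: SimulationConfig,
    rng: np.random.Generator,
    subpop: np.ndarray | None = None,
    ids: Sequence[str] | None = None,
    relatedness_pairs: list[tuple[str, str, float]] | None = None,
) -> SimulatedCohort:
    """Liability-threshold phenotypes plus covariates for given dosages.

    liability = sqrt(h2) * standardized genetic score + covariate effects
    + Gaussian noise filling the variance to 1; case iff liability exceeds
    the 1 - prevalence standard-normal quantile. Age at onset (cases only)
    decreases linearly in liability, truncated to [20, 85] years.
    """
    n = dosages.shape[0]
    h2 = arch.liability_h2
    if subpop is None:
        subpop = _subpop_labels(config, n)
    beta = arch.beta_vector(list(keys))
    g_raw = dosages @ beta
    g_sd = g_raw.std()
    g_std = (g_raw - g_raw.mean()) / g_sd if g_sd > 0 else np.zeros(n)
    cov, cov_contrib = _covariates(rng, n, subpop)
    cov_var = _COV_VAR
    if h2 + cov_var > 1.0:  # rescale covariate effects to keep variance valid
        scale = np.sqrt((1.0 - h2) / cov_var) * 0.999
        cov_contrib = cov_contrib * scale
        cov_var = cov_var * scale**2
    noise_sd = np.sqrt(max(0.0, 1.0 - h2 - cov_var))
    liability = np.sqrt(h2) * g_std + cov_contrib + noise_sd * rng.standard_normal(n)
    # threshold at the liability distribution's own quantile: the liability is
    # not Gaussian when a large-effect rare variant skews the genetic score
    threshold = np.quantile(liability, 1.0 - arch.prevalence)
    phenotype = (liability > threshold).astype(int)
    onset = np.full(n, np.nan)
    cases = phenotype == 1
    onset[cases] = np.clip(
        58.0 - 5.0 * liability[cases] + rng.normal(0, 7, size=int(cases.sum())),
        20.0,
        85.0,
    )
    if ids is None:
        ids = [f"IND{i:06d}" for i in range(n)]
    return SimulatedCohort(
        ids=list(ids),
        variant_keys=list(keys),
        dosages=dosages,
        phenotype=phenotype,
        covariates=cov,
        subpop=subpop,
        liability=liability,
        genetic_score=g_std,
        age_at_onset=onset,
        relatedness_pairs=relatedness_pairs or [],
    )


def simulate_cohort(
    config: SimulationConfig,
    arch: CausalArchitecture,
    n_individuals: int,
    stream: int = 1,
    id_prefix: str = "IND",
) -> SimulatedCohort:
    """Simulate a cohort (genotypes, phenotypes, covariates, relatedness).

    ``stream`` separates cohorts drawn from the same configuration (tuning,
    testing, discovery) while staying reproducible from the single seed. A
    small fraction of individuals is rewritten as relatives (duplicated
    haplotypes) with PI_HAT recorded near 0.5 or 0.25, exercising pruning.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    geno = simulate_genotypes(config, n_individuals, rng)
    haps = geno.haplotypes
    dosages = geno.dosages
    ids = [f"{id_prefix}{i:06d}" for i in range(n_individuals)]
    pairs: list[tuple[str, str, float]] = []
    n_pairs = int(round(config.related_fraction * n_individuals / 2))
    if n_pairs:
        chosen = rng.choice(n_individuals, size=2 * n_pairs, replace=False)
        sizes = config.block_sizes()
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        for k in range(n_pairs):
            a, b = int(chosen[2 * k]), int(chosen[2 * k + 1])
            target = 0.5 if k % 2 == 0 else 0.25
            if target == 0.5:
                haps[2 * b] = haps[2 * a]
            else:  # share one haplotype over half the blocks
                for bi, (st, size) in enumerate(zip(starts, sizes)):
                    if bi % 2 == 0:
                        haps[2 * b, st : st + size] = haps[2 * a, st : st + size]
            dosages[b] = haps[2 * b].astype(np.float64) + haps[2 * b + 1]
            est = float(np.clip(target + rng.normal(0, 0.01), 0.0, 1.0))
            pairs.append((ids[a], ids[b], est))
    return simulate_phenotypes(
        dosages,
        variant_keys(config),
        arch,
        config,
        rng,
        subpop=geno.subpop,
        ids=ids,
        relatedness_pairs=pairs,
    )


class SummaryStatsResult(NamedTuple):
    records: list[SummaryStatRecord]
    n_flagged: int


def generate_summary_stats(
    panel: LDPanel,
    arch: CausalArchitecture,
    n_case: int,
    n_control: int,
    mode: str = "analytic",
    seed: int = 0,
    cohort: SimulatedCohort | None = None,
) -> SummaryStatsResult:
    """Synthetic discovery summary statistics for every panel variant.

    Analytic mode: beta_hat ~ Normal(beta, se^2) with the closed-form
    score-test se; effect-allele frequency equals the panel frequency
    exactly. Cohort mode: per-variant score test on the supplied discovery
    cohort. Monomorphic variants (p(1-p) = 0) are emitted with missing
    statistics and counted as flagged.
    """
    if mode == "analytic":
        if panel is None:
            raise ValueError("analytic mode requires a reference panel")
        keys = list(panel.variants["variant_key"])
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        eaf = panel.variants["eaf"].to_numpy(dtype=float)
        beta = arch.beta_vector(keys)
        N = n_case + n_control
        phi = n_case / N
        pq = eaf * (1.0 - eaf)
        with np.errstate(divide="ignore"):
            se = 1.0 / np.sqrt(2.0 * pq * N * phi * (1.0 - phi))
        bhat = beta + se * rng.standard_normal(len(keys))
        with np.errstate(invalid="ignore"):
            z = np.abs(bhat) / se
        p = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
    elif mode == "cohort":
        if cohort is None:
            raise ValueError("cohort mode requires a simulated discovery cohort")
        D = cohort.dosages
        y = cohort.phenotype.astype(float)
        keys = cohort.variant_keys
        n_case = int(y.sum())
        n_control = int(len(y) - y.sum())
        ybar = y.mean()
        yc = y - ybar
        Dc = D - D.mean(axis=0)
        U = Dc.T @ yc
        V = ybar * (1 - ybar) * np.einsum("ij,ij->j", Dc, Dc)
        with np.errstate(divide="ignore", invalid="ignore"):
            bhat = U / V
            se = 1.0 / np.sqrt(V)
            z = np.abs(U) / np.sqrt(V)
        p = np.clip(2.0 * stats.norm.sf(z), 1e-300, 1.0)
        eaf = D.mean(axis=0) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    records: list[SummaryStatRecord] = []
    n_flagged = 0
    for i, key in enumerate(keys):
        ref, alt = key.split(":")[2], key.split(":")[3]
        if not np.isfinite(se[i]) or se[i] <= 0:
            n_flagged += 1
            records.append(
                SummaryStatRecord(
                    key, alt, ref, float("nan"), float("nan"), float("nan"),
                    float(eaf[i]), n_case, n_control,
                )
            )
            continue
        records.append(
            SummaryStatRecord(
                key, alt, ref, float(bhat[i]), float(se[i]), float(p[i]),
                float(eaf[i]), n_case, n_control,
            )
        )
    return SummaryStatsResult(records, n_flagged)


@dataclass(frozen=True)
class Scenario:
    """The default study conditions: one configuration, one architecture and
    the cohort / discovery sample sizes used throughout the analyses."""

    config: SimulationConfig
    arch: CausalArchitecture
    rare_rule: RareVariantRule
    n_tuning: int = 3_500
    n_test: int = 10_000
    n_case_discovery: int = 60_000
    n_control_discovery: int = 240_000
    prefilter_p: float = 5e-4

    # reproducibility streams
    STREAM_TUNING = 1
    STREAM_TEST = 2


# index layout of the default scenario (block size 20, 45 blocks):
# large-effect rare variants sit mid-block in blocks 1,5,...,33; moderate
# common effects mid-block in even blocks; many small common effects spread
# over the remaining offsets.
_RARE_SPECS: tuple[tuple[int, float, str, tuple[float, float] | float], ...] = (
    (1, 2.0669, "mody", 0.005),        # OR ~7.9, MODY-class
    (5, 0.3075, "non_mody", (0.002, 0.010)),  # OR ~1.36, population-specific
    (9, 0.80, "non_mody", 0.006),
    (13, 0.65, "non_mody", 0.006),
    (17, 0.50, "non_mody", 0.006),
    (21, 0.45, "non_mody", 0.006),
    (25, 0.40, "non_mody", 0.006),
    (29, -0.45, "non_mody", 0.006),
    (33, -0.80, "non_mody", 0.006),
)

# rare variants live in blocks carrying no other causal variant, so the
# common-variant background cannot tag them through within-block LD —
# mirroring rare alleles absent from common-variant SNP lists.
_RARE_BLOCKS = frozenset(b for b, *_ in _RARE_SPECS)


def default_scenario(seed: int = 0) -> Scenario:
    """The frozen default study conditions (see docs/methods.md for rationale)."""
    n_blocks, block_size = 45, 20
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))

    rare_idx = {b: b * block_size + 10 for b, *_ in _RARE_SPECS}
    moderate_blocks = [b for b in range(0, 40, 2) if b not in _RARE_BLOCKS]
    moderate_idx = [b * block_size + 10 for b in moderate_blocks]
    small_idx = []
    for b in range(n_blocks):
        if b in _RARE_BLOCKS:
            continue
        for off in (1, 3, 5, 7, 9, 12, 14, 16, 18):
            small_idx.append(b * block_size + off)
    small_idx = small_idx[:300]

    overrides: dict[int, tuple[float, ...]] = {}
    for b, _, _, freq in _RARE_SPECS:
        vals = (freq, freq) if np.isscalar(freq) else tuple(freq)
        overrides[rare_idx[b]] = vals
    for i in moderate_idx:
        f = float(rng.uniform(0.1, 0.4))
        overrides[i] = (f, f)
    small_freqs = rng.uniform(0.05, 0.5, size=len(small_idx))
    for i, f in zip(small_idx, small_freqs):
        overrides[i] = (float(f), float(f))

    config = SimulationConfig(
        n_variants=n_blocks * block_size,
        n_blocks=n_blocks,
        seed=seed,
        freq_overrides=overrides,
    )
    keys = variant_keys(config)

    common: dict[str, float] = {}
    for i in moderate_idx:
        common[keys[i]] = float(rng.normal(0, 0.08))
    for i in small_idx:
        common[keys[i]] = float(rng.normal(0, 0.025))

    rare: dict[str, RareEffect] = {}
    popspec: set[str] = set()
    for b, beta, gene_class, freq in _RARE_SPECS:
        key = keys[rare_idx[b]]
        rare[key] = RareEffect(beta=beta, gene_class=gene_class)
        if not np.isscalar(freq):
            popspec.add(key)

    arch = CausalArchitecture(
        common_effects=common,
        rare_effects=rare,
        population_specific=frozenset(popspec),
        liability_h2=0.5,
        prevalence=0.3,
    )

    mody_key = keys[rare_idx[1]]
    mody_pos = int(mody_key.split(":")[1])
    rule = RareVariantRule(
        mody_regions=(("1", mody_pos - 1000, mody_pos + 1000),)
    )
    return Scenario(config=config, arch=arch, rare_rule=rule)
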