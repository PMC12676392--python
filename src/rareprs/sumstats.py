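"""GWAS summary-statistic records: METAL-dialect I/O, harmonization and filtering.

A summary-statistic record carries one variant's meta-analysis result on the
log-odds scale. Variant identity is a ``chrom:pos:ref:alt`` key with 1-based
positions, matching the VCF convention used by the LD reference panel.

Harmonization orients every record to the panel's alt allele: records whose
effect allele is the panel ref allele have their log-odds negated and their
effect-allele frequency complemented; records absent from the panel (or with
an allele mismatch) are dropped and counted, never fatal.

The rare-variant selection rule mirrors the carrier definition used for
carrier-aware evaluation: MAF below a ceiling, absolute log-odds above a
floor, and an association p-value threshold that is more lenient inside
monogenic-diabetes (MODY) gene regions than outside them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "RareVariantRule",
    "RareVariantCall",
    "ReadResult",
    "HarmonizeResult",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "prefilter",
    "select_rare_variants",
    "parse_variant_key",
]

#: column order of the METAL-style tab-separated dialect
METAL_COLUMNS = (
    "MarkerName",
    "Allele1",
    "Allele2",
    "Freq1",
    "Effect",
    "StdErr",
    "P-value",
    "N_case",
    "N_control",
)


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Split ``chrom:pos:ref:alt`` into its components (pos as int, 1-based)."""
    chrom, pos, ref, alt = key.split(":")
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's meta-analysis result.

    ``beta`` is the log-odds effect of ``effect_allele``; ``eaf`` its
    frequency. ``beta``/``se``/``p`` may be NaN for variants emitted with
    missing statistics (e.g. monomorphic in the discovery sample).
    """

    variant_key: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: float
    n_case: int
    n_control: int

    @property
    def chrom(self) -> str:
        return self.variant_key.split(":", 1)[0]

    @property
    def pos(self) -> int:
        return int(self.variant_key.split(":")[1])

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(eaf, 1-eaf)."""
        return min(self.eaf, 1.0 - self.eaf)


class ReadResult(NamedTuple):
    records: list[SummaryStatRecord]
    n_skipped: int


class HarmonizeResult(NamedTuple):
    records: list[SummaryStatRecord]
    n_flipped: int
    n_dropped: int


def read_summary_stats(path, dialect: str = "metal") -> ReadResult:
    """Read summary statistics from a tab-separated file.

    Only the ``metal`` dialect is supported. A missing required column is a
    hard error naming the column; rows with non-numeric statistics are
    skipped and counted.
    """
    if dialect != "metal":
        raise ValueError(f"unknown summary-statistic dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"summary-statistic file missing required column {col!r}")

    numeric = {}
    for col in ("Freq1", "Effect", "StdErr", "P-value"):
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("N_case", "N_control"):
        numeric[col] = pd.to_numeric(df[col], errors="coerce")

    records: list[SummaryStatRecord] = []
    n_skipped = 0
    for i in range(len(df)):
        beta = numeric["Effect"].iloc[i]
        se = numeric["StdErr"].iloc[i]
        p = numeric["P-value"].iloc[i]
        eaf = numeric["Freq1"].iloc[i]
        n_case = numeric["N_case"].iloc[i]
        n_control = numeric["N_control"].iloc[i]
        if any(math.isnan(x) for x in (beta, se, p, eaf, n_case, n_control)):
            n_skipped += 1
            continue
        if not (0.0 < p <= 1.0) or se <= 0.0 or not (0.0 <= eaf <= 1.0):
            n_skipped += 1
            continue
        records.append(
            SummaryStatRecord(
                variant_key=str(df["MarkerName"].iloc[i]),
                effect_allele=str(df["Allele1"].iloc[i]),
                other_allele=str(df["Allele2"].iloc[i]),
                beta=float(beta),
                se=float(se),
                p=float(p),
                eaf=float(eaf),
                n_case=int(n_case),
                n_control=int(n_control),
            )
        )
    return ReadResult(records, n_skipped)


def write_summary_stats(records: Iterable[SummaryStatRecord], path) -> None:
    """Write records as METAL-style TSV with 10-significant-digit floats."""

    def fmt(x: float) -> str:
        return "NA" if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.10g}"

    with open(path, "w") as fh:
        fh.write("\t".join(METAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.variant_key,
                        r.effect_allele,
                        r.other_allele,
                        fmt(r.eaf),
                        fmt(r.beta),
                        fmt(r.se),
                        fmt(r.p),
                        str(r.n_case),
                        str(r.n_control),
                    ]
                )
                + "\n"
            )


def harmonize(records: Sequence[SummaryStatRecord], panel) -> HarmonizeResult:
    """Orient records to the panel's alt allele.

    Records whose effect allele equals the panel alt pass through unchanged;
    records whose effect allele equals the panel ref are flipped (beta
    negated, eaf complemented, variant key rewritten to the panel key).
    Records at positions absent from the panel, or with an allele mismatch,
    are dropped and counted.
    """
    by_pos: dict[tuple[str, int], tuple[str, str, str]] = {}
    for key in panel.variants["variant_key"]:
        chrom, pos, ref, alt = parse_variant_key(key)
        by_pos[(chrom, pos)] = (key, ref, alt)

    out: list[SummaryStatRecord] = []
    n_flipped = 0
    n_dropped = 0
    for r in records:
        chrom, pos, _, _ = parse_variant_key(r.variant_key)
        hit = by_pos.get((chrom, pos))
        if hit is None:
            n_dropped += 1
            continue
        key, ref, alt = hit
        if r.effect_allele == alt and r.other_allele == ref:
            if r.variant_key == key:
                out.append(r)
            else:
                out.append(
                    SummaryStatRecord(
                        key, alt, ref, r.beta, r.se, r.p, r.eaf, r.n_case, r.n_control
                    )
                )
        elif r.effect_allele == ref and r.other_allele == alt:
            n_flipped += 1
            out.append(
                SummaryStatRecord(
                    key, alt, ref, -r.beta, r.se, r.p, 1.0 - r.eaf, r.n_case, r.n_control
                )
            )
        else:
            n_dropped += 1
    return HarmonizeResult(out, n_flipped, n_dropped)


def prefilter(
    records: Sequence[SummaryStatRecord], p_max: float = 5e-4
) -> list[SummaryStatRecord]:
    """Keep records with p strictly below ``p_max`` (NaN p never passes)."""
    return [r for r in records if r.p < p_max]


@dataclass(frozen=True)
class RareVariantRule:
    """Selection rule for large-effect rare variants defining carrier sets.

    ``mody_regions`` are (chrom, start, end) intervals, 1-based inclusive on
    both ends to match variant keys (note: not BED half-open).
    """

    maf_max: float = 0.03
    abs_beta_min: float = 0.3
    p_max_mody: float = 1e-6
    p_max_other: float = 1e-9
    mody_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.p_max_mody > self.p_max_other:
            raise ValueError("p_max_mody must exceed p_max_other")
        if not 0.0 < self.maf_max < 0.5:
            raise ValueError("maf_max must lie in (0, 0.5)")

    def in_mody_region(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.mody_regions)


@dataclass(frozen=True)
class RareVariantCall:
    variant_key: str
    effect_allele: str
    beta: float
    direction: str  # "risk" (beta > 0) or "protective" (beta < 0)
    gene_class: str  # "mody" or "non_mody"


def select_rare_variants(
    records: Sequence[SummaryStatRecord], rule: RareVariantRule
) -> list[RareVariantCall]:
    """Apply the rare-variant rule: MAF, |log-odds| and region-aware p cuts.

    Output is sorted by genomic position so the result does not depend on
    record order. Strict inequalities throughout.
    """
    calls: list[RareVariantCall] = []
    for r in records:
        if math.isnan(r.beta) or math.isnan(r.p):
            continue
        if not r.maf < rule.maf_max:
            continue
        if not abs(r.beta) > rule.abs_beta_min:
            continue
        chrom, pos, _, _ = parse_variant_key(r.variant_key)
        mody = rule.in_mody_region(chrom, pos)
        p_cut = rule.p_max_mody if mody else rule.p_max_other
        if not r.p < p_cut:
            continue
        calls.append(
            RareVariantCall(
                variant_key=r.variant_key,
                effect_allele=r.effect_allele,
                beta=r.beta,
                direction="risk" if r.beta > 0 else "protective",
                gene_class="mody" if mody else "non_mody",
            )
        )
    calls.sort(key=lambda c: (c.variant_key.split(":")[0], int(c.variant_key.split(":")[1]), c.variant_key))
    return calls
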