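"""LD reference panel: dosage storage, r-squared queries, panel and sample filters.

The panel holds an individuals x variants dosage matrix (values in [0, 2],
NaN = missing) plus ordered variant metadata. LD between two variants is the
squared Pearson correlation of dosages over pairwise-complete individuals;
an undefined r-squared (monomorphic partner) is reported as NaN and treated
as below any clumping threshold.

Relatedness pruning removes individuals until no pair with PI_HAT above the
threshold remains, by iteratively deleting a maximum-degree node of the
relatedness graph (ties broken by lexicographically smallest ID). This is
deterministic and matches the minimum vertex cover on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import parse_variant_key

__all__ = [
    "LDPanel",
    "RelatednessGraph",
    "panel_from_dosages",
    "apply_mac_filter",
    "compute_r2",
    "neighbors_within",
    "prune_related",
]


class LDPanel:
    """Reference-panel dosages plus variant metadata.

    ``variants`` must contain columns ``variant_key, chrom, pos, ref, alt,
    eaf, maf, mac`` with positions nondecreasing within each chromosome.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variants: pd.DataFrame,
        individual_ids: Sequence[str] | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants matrix")
        if dosages.shape[1] != len(variants):
            raise ValueError("variant metadata length does not match dosage columns")
        with np.errstate(invalid="ignore"):
            if np.nanmin(dosages, initial=0.0) < 0 or np.nanmax(dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.dosages = dosages
        self.variants = variants.reset_index(drop=True)
        if individual_ids is None:
            individual_ids = [f"REF{i:06d}" for i in range(dosages.shape[0])]
        if len(individual_ids) != dosages.shape[0]:
            raise ValueError("individual_ids length does not match dosage rows")
        self.individual_ids = list(individual_ids)
        self._key_to_idx = {k: i for i, k in enumerate(self.variants["variant_key"])}
        self._has_missing = bool(np.isnan(dosages).any())
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) >= 0):
                raise ValueError(f"positions not nondecreasing on chromosome {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_key: str) -> int:
        try:
            return self._key_to_idx[variant_key]
        except KeyError:
            raise KeyError(f"variant {variant_key} not in panel") from None

    def __contains__(self, variant_key: str) -> bool:
        return variant_key in self._key_to_idx


def panel_from_dosages(
    dosages: np.ndarray,
    variant_keys: Sequence[str],
    individual_ids: Sequence[str] | None = None,
) -> LDPanel:
    """Build a panel, deriving eaf/maf/mac from the dosage matrix itself."""
    dosages = np.asarray(dosages, dtype=float)
    meta = _variant_meta(dosages, variant_keys)
    return LDPanel(dosages, meta, individual_ids)


def _variant_meta(dosages: np.ndarray, variant_keys: Sequence[str]) -> pd.DataFrame:
    rows = []
    for j, key in enumerate(variant_keys):
        chrom, pos, ref, alt = parse_variant_key(key)
        col = dosages[:, j]
        obs = col[~np.isnan(col)]
        n = obs.size
        alt_count = float(obs.sum())
        eaf = alt_count / (2 * n) if n else np.nan
        maf = min(eaf, 1.0 - eaf) if n else np.nan
        mac = int(round(min(alt_count, 2 * n - alt_count))) if n else 0
        rows.append((key, chrom, pos, ref, alt, eaf, maf, mac))
    return pd.DataFrame(
        rows, columns=["variant_key", "chrom", "pos", "ref", "alt", "eaf", "maf", "mac"]
    )


def apply_mac_filter(panel: LDPanel, min_mac: int = 3) -> LDPanel:
    """Retain variants with minor allele count >= ``min_mac``.

    Mirrors the reference-panel quality step of removing variants with MAC
    below the cutoff; idempotent.
    """
    keep = (panel.variants["mac"] >= min_mac).to_numpy()
    return LDPanel(
        panel.dosages[:, keep],
        panel.variants.loc[keep].reset_index(drop=True),
        panel.individual_ids,
    )


def compute_r2(panel: LDPanel, a: str, b: str) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete rows.

    Returns NaN when either variant has zero variance among the complete
    pairs (undefined LD, treated as below any threshold).
    """
    ia, ib = panel.index_of(a), panel.index_of(b)
    return _r2_pair(panel.dosages[:, ia], panel.dosages[:, ib])


def _r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete individuals for r2")
    xm, ym = x[mask], y[mask]
    xc = xm - xm.mean()
    yc = ym - ym.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


def r2_one_vs_many(panel: LDPanel, lead_idx: int, other_idx: np.ndarray) -> np.ndarray:
    """Vectorized r-squared of one variant against many (NaN where undefined)."""
    if other_idx.size == 0:
        return np.empty(0)
    x = panel.dosages[:, lead_idx]
    Y = panel.dosages[:, other_idx]
    if not panel._has_missing:
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        vx = float(xc @ xc)
        vy = np.einsum("ij,ij->j", Yc, Yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (xc @ Yc) ** 2 / (vx * vy)
        r2[vy == 0.0] = np.nan
        if vx == 0.0:
            r2[:] = np.nan
        return np.minimum(r2, 1.0)
    return np.array([_r2_pair(x, Y[:, j]) for j in range(Y.shape[1])])


def neighbors_within(panel: LDPanel, lead: str, window_kb: float) -> list[str]:
    """Same-chromosome variants within +/- window_kb of the lead (inclusive
    boundary), excluding the lead itself, in position order."""
    i = panel.index_of(lead)
    chrom = panel.variants["chrom"].iloc[i]
    pos = panel.variants["pos"].iloc[i]
    span = window_kb * 1000.0
    v = panel.variants
    mask = (v["chrom"] == chrom) & ((v["pos"] - pos).abs() <= span)
    mask.iloc[i] = False
    out = v.loc[mask].sort_values("pos", kind="stable")
    return out["variant_key"].tolist()


@dataclass
class RelatednessGraph:
    """Undirected relatedness graph: nodes are individual IDs, edges carry
    PI_HAT (estimated genome fraction shared identical-by-descent)."""

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for a, b, pihat in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a}")
            if not 0.0 <= pihat <= 1.0:
                raise ValueError("PI_HAT must lie in [0, 1]")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "RelatednessGraph":
        pairs = list(pairs)
        nodes = sorted({x for a, b, _ in pairs for x in (a, b)})
        return cls(nodes=nodes, edges=pairs)


def prune_related(graph: RelatednessGraph, pi_hat_max: float = 0.1875) -> list[str]:
    """Return individual IDs surviving relatedness pruning.

    Edges with PI_HAT <= ``pi_hat_max`` are ignored; then a maximum-degree
    node (ties: lexicographically smallest ID) is deleted repeatedly until no
    edge remains. The survivors contain no pair above the threshold.
    """
    adj: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for a, b, pihat in graph.edges:
        if pihat > pi_hat_max:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    removed: set[str] = set()
    while True:
        deg = {n: len(nb) for n, nb in adj.items() if n not in removed and nb}
        if not deg or max(deg.values()) == 0:
            break
        max_deg = max(deg.values())
        victim = min(n for n, d in deg.items() if d == max_deg)
        removed.add(victim)
        for nb in adj[victim]:
            adj[nb].discard(victim)
        adj[victim] = set()
    survivors = [n for n in graph.nodes if n not in removed]
    # postcondition: no remaining edge above threshold
    keep = set(survivors)
    assert not any(
        a in keep and b in keep and pihat > pi_hat_max for a, b, pihat in graph.edges
    )
    return survivors
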