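"""Independent reference implementations used as test oracles."""

from __future__ import annotations

import numpy as np


def oracle_clump(records, panel, setting):
    """O(n^2) greedy clumping against a full corrcoef r2 matrix.

    Deliberately structured unlike the package implementation (no windowed
    search, no incremental vectorization): order candidates by (p, chrom,
    pos, key), promote, and linearly scan the unclaimed set.
    """
    keys = [r.variant_key for r in records]
    idx = [panel.index_of(k) for k in keys]
    D = panel.dosages[:, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(D.T) ** 2
    sd = D.std(axis=0)
    chrom = [panel.variants["chrom"].iloc[i] for i in idx]
    pos = [int(panel.variants["pos"].iloc[i]) for i in idx]
    p = [r.p for r in records]
    order = sorted(range(len(records)), key=lambda i: (p[i], chrom[i], pos[i], keys[i]))
    span = setting.base_window_kb / setting.r2_threshold * 1000.0
    unclaimed = set(range(len(records)))
    leads = []
    for i in order:
        if i not in unclaimed:
            continue
        unclaimed.discard(i)
        leads.append(keys[i])
        for j in list(unclaimed):
            if chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > span:
                continue
            if sd[i] == 0 or sd[j] == 0:
                continue  # undefined r2 never claims
            if R[i, j] >= setting.r2_threshold:
                unclaimed.discard(j)
    return leads
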