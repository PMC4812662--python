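"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives an expected result by the most direct method
available (all-pairs graph closure, per-character scanning, per-base
bitmaps) and never shares code with the implementation it checks.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from cnvpol.merge import reciprocal_overlap


def brute_force_clusters(intervals: Sequence[Tuple[str, int, int]],
                         ro_min: float) -> List[List[int]]:
    """Transitive closure over the explicit all-pairs RO graph (O(n^2))."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if intervals[i][0] != intervals[j][0]:
                continue
            if reciprocal_overlap(intervals[i][1:], intervals[j][1:]) >= ro_min:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    return sorted(comps)


def brute_force_microhomology(seq: str, start: int, end: int,
                              cap: int = 500) -> Tuple[int, int, int]:
    """Character-by-character junction microhomology scan."""
    seq = seq.upper()
    right = 0
    while (right < cap and end + right < len(seq)
           and seq[start + right] == seq[end + right]
           and seq[start + right] != "N"):
        right += 1
    left = 0
    while (left < cap and left < start
           and seq[start - 1 - left] == seq[end - 1 - left]
           and seq[start - 1 - left] != "N"):
        left += 1
    return left, right, left + right


def bitmap_te_coverage(chrom: str, start: int, end: int,
                       te_rows) -> float:
    """Per-base bitmap of TE cover over the interval."""
    mask = np.zeros(end - start, dtype=bool)
    for r in te_rows.itertuples(index=False):
        if r.chrom != chrom:
            continue
        s, e = max(int(r.start), start), min(int(r.end), end)
        if e > s:
            mask[s - start:e - start] = True
    return float(mask.mean())


def bitmap_gene_category(event: Tuple[int, int], gene) -> str:
    """Per-base annotation bitmap oracle for the gene-impact category."""
    s, e = event
    lo, hi = gene.start, gene.end
    full = s <= lo and hi <= e

    def covered(ivs):
        pos = set()
        for a, b in ivs:
            pos.update(range(a, b))
        return any(s <= p < e for p in pos)

    if full:
        return "full"
    if covered(gene.cds):
        return "partial_cds"
    if covered(gene.utr5) or covered(gene.utr3):
        return "utr_only"
    return "intron_only"
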