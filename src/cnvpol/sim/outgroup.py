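"""Outgroup synthesis: ancestral haplotype, divergence, gaps, anchors.

The ancestral haplotype is the reference minus all insertion-state events
(deletion-state events are ancestral sequence the reference kept, so they
stay). The outgroup is the ancestral haplotype after per-site substitutions
at ``outgroup_divergence``, small (1-3 bp) indels at ``outgroup_indel_rate``
and assembly gaps — runs of N at ``outgroup_gap_rate`` expected gaps per
chromosome. One synteny anchor is emitted per gene present in both genomes,
with exact coordinates from the simulator's own coordinate bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ..config import SimConfig
from ..io import Genome
from .events import TruthRecord
from .reference import GenomePack, _rng, mutate_subs, random_seq

_N = ord("N")


@dataclass
class ChromMap:
    """Piecewise-linear reference -> outgroup coordinate map."""

    ins_starts: np.ndarray   # insertion-state intervals on the reference
    ins_ends: np.ndarray
    ins_cumlen: np.ndarray   # cumulative removed bp up to and incl. each
    indel_pos: np.ndarray    # ancestral positions of outgroup indels
    indel_cum: np.ndarray    # cumulative out-minus-anc offset after each

    def ref_to_anc(self, x: int) -> int:
        i = int(np.searchsorted(self.ins_starts, x, side="right"))
        if i > 0 and x < self.ins_ends[i - 1]:
            # inside a removed insertion: collapse to its left edge
            x = int(self.ins_starts[i - 1])
            i -= 1
        removed = int(self.ins_cumlen[i - 1]) if i > 0 else 0
        return x - removed

    def anc_to_out(self, y: int) -> int:
        i = int(np.searchsorted(self.indel_pos, y, side="right"))
        delta = int(self.indel_cum[i - 1]) if i > 0 else 0
        return max(0, y + delta)

    def ref_to_out(self, x: int) -> int:
        return self.anc_to_out(self.ref_to_anc(x))


@dataclass
class OutgroupPack:
    outgroup: Genome
    ancestral: Genome
    anchors: pd.DataFrame   # gene_id, ref_chrom/start/end, out_chrom/start/end, strand
    gaps: pd.DataFrame      # chrom, start, end (outgroup coordinates)
    maps: Dict[str, ChromMap] = field(default_factory=dict)


def _remove_intervals(seq: np.ndarray,
                      intervals: List[Tuple[int, int]]) -> np.ndarray:
    if not intervals:
        return seq.copy()
    keep = np.ones(len(seq), dtype=bool)
    for s, e in intervals:
        keep[s:e] = False
    return seq[keep]


def mutate_outgroup(pack: GenomePack, truth: List[TruthRecord],
                    config: SimConfig | None = None,
                    flank: int = 2000) -> OutgroupPack:
    """Build the outgroup genome; fills truth.gap_overlap_frac in place."""
    config = config or pack.config
    rng = _rng(config, 3)
    ins_by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in pack.genome}
    for t in truth:
        if t.ancestral_state == "insertion":
            ins_by_chrom[t.chrom].append((t.ref_start, t.ref_end))
    outgroup: Genome = {}
    ancestral: Genome = {}
    maps: Dict[str, ChromMap] = {}
    gap_rows = []
    for chrom, refseq in pack.genome.items():
        ins = sorted(ins_by_chrom[chrom])
        anc = _remove_intervals(refseq, ins)
        ancestral[chrom] = anc
        mutated = mutate_subs(rng, anc, config.outgroup_divergence)

        # small indels, tracked so anchor coordinates stay exact
        n_indels = rng.poisson(config.outgroup_indel_rate * len(anc))
        pos = np.unique(rng.integers(100, len(anc) - 100, size=n_indels)) \
            if n_indels else np.array([], dtype=np.int64)
        pieces, deltas, prev = [], [], 0
        for p in pos.tolist():
            length = int(rng.integers(1, 4))
            pieces.append(mutated[prev:p])
            if rng.random() < 0.5 and p + length < len(anc):  # deletion
                prev = p + length
                deltas.append((p, -length))
            else:  # insertion
                pieces.append(random_seq(rng, length, 0.5))
                prev = p
                deltas.append((p, length))
        pieces.append(mutated[prev:])
        out = np.concatenate(pieces) if pieces else mutated
        indel_pos = np.array([p for p, _ in deltas], dtype=np.int64)
        indel_cum = np.cumsum([d for _, d in deltas]).astype(np.int64) \
            if deltas else np.array([], dtype=np.int64)

        # assembly gaps: runs of N in the outgroup assembly
        n_gaps = rng.poisson(config.outgroup_gap_rate)
        for _ in range(n_gaps):
            glen = int(rng.integers(2000, 6001))
            if len(out) <= glen + 200:
                continue
            g = int(rng.integers(100, len(out) - glen - 100))
            out[g:g + glen] = _N
            gap_rows.append((chrom, g, g + glen))

        outgroup[chrom] = out
        starts = np.array([s for s, _ in ins], dtype=np.int64)
        ends = np.array([e for _, e in ins], dtype=np.int64)
        maps[chrom] = ChromMap(
            ins_starts=starts, ins_ends=ends,
            ins_cumlen=np.cumsum(ends - starts).astype(np.int64)
            if len(ins) else np.array([], dtype=np.int64),
            indel_pos=indel_pos, indel_cum=indel_cum)

    gaps = pd.DataFrame(sorted(gap_rows), columns=["chrom", "start", "end"])

    # synteny anchors: genes surviving in the ancestral lineage
    anchor_rows = []
    for g in pack.genes:
        m = maps[g.chrom]
        fully_inside = any(s <= g.start and g.end <= e
                           for s, e in ins_by_chrom[g.chrom])
        if fully_inside:
            continue
        out_s, out_e = m.ref_to_out(g.start), m.ref_to_out(g.end)
        if out_e <= out_s:
            continue
        anchor_rows.append((g.gene_id, g.chrom, g.start, g.end,
                            g.chrom, out_s, out_e, "+"))
    anchors = pd.DataFrame(
        anchor_rows, columns=["gene_id", "ref_chrom", "ref_start", "ref_end",
                              "out_chrom", "out_start", "out_end", "strand"])

    # per-event gap cover of the projected outgroup window (truth bookkeeping)
    gap_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for row in gaps.itertuples(index=False):
        gap_by_chrom.setdefault(row.chrom, []).append((row.start, row.end))
    for t in truth:
        m = maps[t.chrom]
        ws = m.ref_to_out(max(0, t.ref_start - flank))
        we = m.ref_to_out(min(len(pack.genome[t.chrom]), t.ref_end + flank))
        if we <= ws:
            t.gap_overlap_frac = 0.0
            continue
        cover = sum(max(0, min(we, ge) - max(ws, gs))
                    for gs, ge in gap_by_chrom.get(t.chrom, []))
        t.gap_overlap_frac = cover / (we - ws)

    return OutgroupPack(outgroup=outgroup, ancestral=ancestral,
                        anchors=anchors, gaps=gaps, maps=maps)
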