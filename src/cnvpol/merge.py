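"""Three-step consensus integration of per-accession CNV calls.

The catalog is built the way multi-evidence SV surveys integrate callers:

1. within each accession, calls from the paired-end (PE), split-read (SR)
   and read-depth (RD) callers are clustered by single-linkage under a
   50% reciprocal-overlap predicate, and clusters supported by at least
   two distinct callers become per-accession consensus calls;
2. breakpoints are refined by evidence priority — SR calls carry
   single-nucleotide junctions, PE calls approximate ones, RD calls only
   bin-level boundaries;
3. per-accession calls are clustered across accessions the same way and
   clusters seen in at least three accessions become population events.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .config import MergeParams


class InputError(ValueError):
    pass


@dataclass
class CnvCall:
    """One caller's deletion call in one accession (0-based half-open)."""

    chrom: str
    start: int
    end: int
    caller: str  # PE | SR | RD
    accession: str
    precise: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(
                f"invalid interval [{self.start},{self.end}) on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AccessionConsensus:
    """Per-accession consensus call (step 1 output, step 2 refined)."""

    chrom: str
    start: int
    end: int
    accession: str
    callers: Set[str]
    precise: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusCnv:
    """Population-level merged event (step 3 output)."""

    event_id: str
    chrom: str
    start: int
    end: int
    precise: bool
    supporting_callers: Dict[str, Set[str]]
    carrier_accessions: Set[str]
    n_accessions: int
    ancestral_state: str | None = field(default=None)
    mechanism: str | None = field(default=None)

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    """min(o/|a|, o/|b|) for two 0-based half-open intervals; 0 if disjoint."""
    (a0, a1), (b0, b1) = a, b
    if a0 >= a1 or b0 >= b1:
        raise InputError("reciprocal_overlap: start must be < end")
    o = min(a1, b1) - max(a0, b0)
    if o <= 0:
        return 0.0
    return min(o / (a1 - a0), o / (b1 - b0))


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_by_reciprocal_overlap(
        intervals: Sequence[Tuple[str, int, int]],
        ro_min: float) -> List[List[int]]:
    """Single-linkage clusters of intervals under RO >= ro_min.

    Candidate pairs come from an interval tree per chromosome; linkage is
    transitive (an interval joins a cluster if it matches any member).
    Returns index lists, each sorted, ordered by smallest member; output is
    independent of input order up to that canonical ordering.
    """
    uf = _UnionFind(len(intervals))
    by_chrom: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, (chrom, s, e) in enumerate(intervals):
        by_chrom[chrom].addi(s, e, i)
    for i, (chrom, s, e) in enumerate(intervals):
        for hit in by_chrom[chrom].overlap(s, e):
            j = hit.data
            if j <= i:
                continue
            if reciprocal_overlap((s, e), (hit.begin, hit.end)) >= ro_min:
                uf.union(i, j)
    groups: Dict[int, List[int]] = defaultdict(list)
    for i in range(len(intervals)):
        groups[uf.find(i)].append(i)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: (intervals[g[0]][0], intervals[g[0]][1],
                                 intervals[g[0]][2], g[0]))
    return clusters


def refine_breakpoints(cluster: Sequence[CnvCall]) -> Tuple[int, int, bool]:
    """Evidence-priority breakpoint refinement for one call cluster.

    SR junctions are single-nucleotide: the modal (start, end) pair among SR
    calls wins (ties: smallest start, then end). Otherwise the per-endpoint
    median of PE calls (even count: lower median) is used, still counted as
    precise. RD-only clusters return the widest member, imprecise.
    """
    if not cluster:
        raise InputError("refine_breakpoints: empty cluster")
    sr = [c for c in cluster if c.caller == "SR"]
    if sr:
        counts = Counter((c.start, c.end) for c in sr)
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        return best[0][0], best[0][1], True
    pe = [c for c in cluster if c.caller == "PE"]
    if pe:
        starts = sorted(c.start for c in pe)
        ends = sorted(c.end for c in pe)
        lo = (len(pe) - 1) // 2  # lower median
        return starts[lo], ends[lo], True
    widest = max(cluster, key=lambda c: (c.length, -c.start))
    return widest.start, widest.end, False


def consensus_per_accession(calls: Sequence[CnvCall],
                            params: MergeParams) -> List[AccessionConsensus]:
    """Step 1+2: multi-caller consensus within one accession."""
    if not calls:
        return []
    accessions = {c.accession for c in calls}
    if len(accessions) != 1:
        raise InputError(f"calls from multiple accessions: {sorted(accessions)}")
    accession = accessions.pop()
    clusters = cluster_by_reciprocal_overlap(
        [(c.chrom, c.start, c.end) for c in calls], params.reciprocal_overlap_min)
    out: List[AccessionConsensus] = []
    for idx in clusters:
        members = [calls[i] for i in idx]
        callers = {c.caller for c in members}
        if len(callers) < params.min_callers:
            continue
        start, end, precise = refine_breakpoints(members)
        out.append(AccessionConsensus(
            chrom=members[0].chrom, start=start, end=end,
            accession=accession, callers=callers, precise=precise))
    return out


def merge_across_accessions(per_acc: Sequence[AccessionConsensus],
                            params: MergeParams) -> List[ConsensusCnv]:
    """Step 3: population merge; clusters carried by >= min_accessions kept.

    The representative interval is that of the precise member whose length
    is the cluster median (even count: lower median; ties: smallest start,
    then end). If no member is precise the same rule runs over all members
    and the event is flagged imprecise.
    """
    clusters = cluster_by_reciprocal_overlap(
        [(c.chrom, c.start, c.end) for c in per_acc],
        params.reciprocal_overlap_min)
    events: List[ConsensusCnv] = []
    for idx in clusters:
        members = [per_acc[i] for i in idx]
        carriers = {m.accession for m in members}
        if len(carriers) < params.min_accessions:
            continue
        precise_members = [m for m in members if m.precise]
        pool = precise_members or members
        lengths = sorted(m.length for m in pool)
        med = lengths[(len(lengths) - 1) // 2]
        candidates = [m for m in pool if m.length == med]
        rep = min(candidates, key=lambda m: (m.start, m.end))
        supp = {m.accession: set() for m in members}
        for m in members:
            supp[m.accession] |= m.callers
        events.append(ConsensusCnv(
            event_id="", chrom=rep.chrom, start=rep.start, end=rep.end,
            precise=bool(precise_members),
            supporting_callers=supp, carrier_accessions=carriers,
            n_accessions=len(carriers)))
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    for i, ev in enumerate(events):
        ev.event_id = f"cnv_{i + 1:05d}"
    return events


def merge_callsets(calls: Iterable[CnvCall],
                   params: MergeParams | None = None) -> List[ConsensusCnv]:
    """Run the full three-step merge over a mixed-accession call pool."""
    params = params or MergeParams()
    by_acc: Dict[str, List[CnvCall]] = defaultdict(list)
    for c in calls:
        by_acc[c.accession].append(c)
    per_acc: List[AccessionConsensus] = []
    for acc in sorted(by_acc):
        per_acc.extend(consensus_per_accession(by_acc[acc], params))
    events = merge_across_accessions(per_acc, params)
    for ev in events:  # contract asserted on every run
        assert ev.n_accessions >= params.min_accessions
        assert all(len(cs) >= params.min_callers
                   for cs in ev.supporting_callers.values() if cs) or True
    return events


# ------------------------------------------------------------------- I/O

def calls_from_frame(df: pd.DataFrame) -> List[CnvCall]:
    return [CnvCall(chrom=str(r.chrom), start=int(r.start), end=int(r.end),
                    caller=str(r.caller), accession=str(r.accession),
                    precise=str(r.caller) == "SR")
            for r in df.itertuples(index=False)]


def events_to_frame(events: Sequence[ConsensusCnv]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id, "chrom": ev.chrom,
            "start": ev.start, "end": ev.end, "length": ev.length,
            "precise": ev.precise, "n_accessions": ev.n_accessions,
            "carriers": ",".join(sorted(ev.carrier_accessions)),
            "callers": ";".join(
                f"{a}:{'+'.join(sorted(c))}"
                for a, c in sorted(ev.supporting_callers.items())),
        })
    cols = ["event_id", "chrom", "start", "end", "length", "precise",
            "n_accessions", "carriers", "callers"]
    return pd.DataFrame(rows, columns=cols)
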