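"""Benchmarking helpers: match pipeline output to simulator truth.

Matching is one-to-one by best reciprocal overlap (>= 0.5 by default),
the standard criterion for SV call concordance. All accuracy figures the
analysis scripts and the acceptance run report are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

from .merge import reciprocal_overlap


@dataclass
class MatchResult:
    pairs: Dict[str, str] = field(default_factory=dict)  # truth_id -> event_id
    n_truth: int = 0
    n_events: int = 0
    recall: float = 0.0
    precision: float = 0.0
    exact_fraction: float = 0.0  # matched events with exact breakpoints


def match_to_truth(events, truth, ro_min: float = 0.5) -> MatchResult:
    res = MatchResult(n_truth=len(truth), n_events=len(events))
    cands = []
    for t in truth:
        for ev in events:
            if ev.chrom != t.chrom:
                continue
            ro = reciprocal_overlap((t.ref_start, t.ref_end),
                                    (ev.start, ev.end))
            if ro >= ro_min:
                cands.append((ro, t.event_id, ev))
    cands.sort(key=lambda c: (-c[0], c[1], c[2].event_id))
    used_truth, used_ev = set(), set()
    exact = 0
    truth_by_id = {t.event_id: t for t in truth}
    for ro, tid, ev in cands:
        if tid in used_truth or ev.event_id in used_ev:
            continue
        used_truth.add(tid)
        used_ev.add(ev.event_id)
        res.pairs[tid] = ev.event_id
        t = truth_by_id[tid]
        if ev.start == t.ref_start and ev.end == t.ref_end:
            exact += 1
    if res.n_truth:
        res.recall = len(res.pairs) / res.n_truth
    if res.n_events:
        res.precision = len(res.pairs) / res.n_events
    if res.pairs:
        res.exact_fraction = exact / len(res.pairs)
    return res


def polarity_accuracy(polarized, truth, pairs: Dict[str, str],
                      gap_threshold: float = 0.1) -> Dict[str, float]:
    """Accuracy of the ancestral-state call on matched gap-free events,
    plus the fraction of gap-overlapping events classified undefined."""
    pol_by_id = {p.event_id: p for p in polarized}
    truth_by_id = {t.event_id: t for t in truth}
    correct = total = 0
    gap_total = gap_undefined = 0
    for tid, eid in pairs.items():
        t, p = truth_by_id[tid], pol_by_id.get(eid)
        if p is None:
            continue
        if t.gap_overlap_frac > gap_threshold:
            gap_total += 1
            gap_undefined += p.ancestral_state == "undefined"
            continue
        total += 1
        correct += p.ancestral_state == t.ancestral_state
    return {
        "accuracy": correct / total if total else float("nan"),
        "n_gap_free": total,
        "n_gap_overlapping": gap_total,
        "gap_undefined_fraction": (gap_undefined / gap_total
                                   if gap_total else float("nan")),
    }


def mechanism_accuracy(mech_calls, truth,
                       pairs: Dict[str, str]) -> Dict[str, object]:
    mech_by_id = {m.event_id: m for m in mech_calls}
    truth_by_id = {t.event_id: t for t in truth}
    per_class: Dict[str, List[int]] = {}
    correct = total = 0
    confusions = []
    for tid, eid in pairs.items():
        t, m = truth_by_id[tid], mech_by_id.get(eid)
        if m is None:
            continue
        total += 1
        hit = m.mechanism == t.mechanism
        correct += hit
        per_class.setdefault(t.mechanism, [0, 0])
        per_class[t.mechanism][0] += hit
        per_class[t.mechanism][1] += 1
        if not hit:
            confusions.append((tid, t.mechanism, m.mechanism))
    return {
        "accuracy": correct / total if total else float("nan"),
        "per_class": {k: v[0] / v[1] for k, v in sorted(per_class.items())},
        "confusions": confusions,
        "n": total,
    }


def insertion_share(polarized) -> Dict[str, float]:
    """Estimated insertion fraction among events with a defined state."""
    counts = {"insertion": 0, "deletion": 0, "undefined": 0}
    for p in polarized:
        counts[p.ancestral_state] += 1
    defined = counts["insertion"] + counts["deletion"]
    return {
        "insertion_share": counts["insertion"] / defined if defined else float("nan"),
        "n_defined": defined,
        "n_undefined": counts["undefined"],
        "n_total": len(list(polarized)),
    }
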