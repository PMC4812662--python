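"""Formation-mechanism classification from breakpoint junction signatures.

Each deletion-relative-to-reference event is labelled by the diagnostic
sequence signature of the rearrangement that created it:

* VNTR — both breakpoints inside one annotated tandem array and the event
  length an integer number of repeat periods (array expansion/contraction);
* MEI — the event body is an annotated transposable-element copy (mobile
  element insertions also leave a short target-site duplication, which shows
  up as junction microhomology);
* NAHR — extended (>= 50 bp), highly identical (>= 90%) homology spanning
  the two junctions, the footprint of non-allelic homologous recombination;
* NHR — little or no junction homology: blunt ends (NHEJ) or 1-10 bp
  microhomology (MMEJ);
* ambiguous — junction homology in the no-man's-land between the NHR and
  NAHR definitions, imprecise breakpoints, or uninformative (N-rich) windows.

Precedence is VNTR -> MEI -> NAHR -> NHR: body signatures are more specific
than junction signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import MechanismParams
from .io import Genome

_N = ord("N")


class InputError(ValueError):
    pass


@dataclass
class MechanismCall:
    event_id: str
    mechanism: str  # NAHR | NHR | MEI | VNTR | ambiguous
    microhomology_len: int = 0
    homology_len: int = 0
    homology_identity: float = 0.0
    te_fraction: float = 0.0
    te_family: str = ""
    vntr_period: int | None = None
    nhr_subtype: str = ""  # NHEJ (blunt) vs MMEJ (1-10 bp microhomology)
    reason: str = ""


def _norm(a: np.ndarray) -> np.ndarray:
    """Uppercase ASCII in place-free fashion (case-insensitive matching)."""
    out = a.copy()
    lower = (out >= 97) & (out <= 122)
    out[lower] -= 32
    return out


def _match_run(a: np.ndarray, b: np.ndarray) -> int:
    """Length of the common prefix of a and b; N never matches."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    a, b = _norm(a[:n]), _norm(b[:n])
    ok = (a == b) & (a != _N) & (b != _N)
    bad = np.flatnonzero(~ok)
    return int(bad[0]) if len(bad) else n


def junction_microhomology(seq: np.ndarray, start: int, end: int,
                           cap: int = 500) -> Tuple[int, int, int]:
    """Exact microhomology shared by the two junctions of a deletion.

    right = longest common prefix of seq[start:] and seq[end:];
    left  = longest common suffix of seq[:start] and seq[:end];
    both capped at ``cap``. Returns (left, right, left+right).
    """
    if not (0 <= start < end <= len(seq)):
        raise InputError(f"interval [{start},{end}) out of bounds")
    w = min(cap, len(seq) - end)
    right = _match_run(seq[start:start + w], seq[end:end + w])
    w = min(cap, start)
    left = _match_run(seq[start - w:start][::-1], seq[end - w:end][::-1])
    return left, right, left + right


def _threshold_run(a: np.ndarray, b: np.ndarray,
                   min_identity: float) -> Tuple[int, int]:
    """Longest homologous prefix at cumulative identity >= threshold.

    Substitution-only comparison (no indel tolerance). The run must end on
    a match, and any extension beyond the initial exact-match prefix must
    itself reach the identity threshold — otherwise a long microhomology
    followed by random sequence would masquerade as extended homology.
    Returns (length, matches in that prefix).
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0, 0
    a, b = _norm(a[:n]), _norm(b[:n])
    m = ((a == b) & (a != _N) & (b != _N)).astype(np.int64)
    cum = np.cumsum(m)
    frac = cum / np.arange(1, n + 1)
    ok = np.flatnonzero((frac >= min_identity) & (m == 1))
    if len(ok) == 0:
        return 0, 0
    exact = int(np.flatnonzero(m == 0)[0]) if (m == 0).any() else n
    L = int(ok[-1]) + 1
    while L > exact:
        tail = (cum[L - 1] - (cum[exact - 1] if exact else 0)) / (L - exact)
        if tail >= min_identity:
            break
        # trim to the previous qualifying end
        prev = ok[ok < L - 1]
        if len(prev) == 0:
            L = 0
            break
        L = int(prev[-1]) + 1
    if L > exact:
        return L, int(cum[L - 1])
    return exact, exact


def flanking_homology(seq: np.ndarray, start: int, end: int,
                      params: MechanismParams | None = None,
                      ) -> Tuple[int, float]:
    """Extended homology between the two junctions of a deletion.

    Scans outward from the junction in both directions: the windows
    beginning at start/end (right) and the windows ending at start/end
    (left), each up to ``homology_scan_window`` bp, extending while the
    cumulative identity stays above ``nahr_min_identity``. Returns
    (left_len + right_len, identity over those spans).
    """
    params = params or MechanismParams()
    if not (0 <= start < end <= len(seq)):
        raise InputError(f"interval [{start},{end}) out of bounds")
    w = min(params.homology_scan_window, len(seq) - end)
    right_len, right_m = _threshold_run(
        seq[start:start + w], seq[end:end + w], params.nahr_min_identity)
    w = min(params.homology_scan_window, start)
    left_len, left_m = _threshold_run(
        seq[start - w:start][::-1], seq[end - w:end][::-1],
        params.nahr_min_identity)
    total = left_len + right_len
    identity = (left_m + right_m) / total if total else 0.0
    return total, identity


def te_coverage(chrom: str, start: int, end: int,
                te: pd.DataFrame) -> Tuple[float, str]:
    """Fraction of [start,end) covered by the union of TE annotations.

    best_family is the family of the single element with the largest
    overlap (ties: lexicographically smallest family name).
    """
    if start >= end:
        raise InputError("te_coverage: empty interval")
    sub = te[(te["chrom"] == chrom) & (te["end"] > start) & (te["start"] < end)]
    if sub.empty:
        return 0.0, ""
    ivs = sorted((max(int(s), start), min(int(e), end), str(f))
                 for s, e, f in zip(sub["start"], sub["end"], sub["family"]))
    best_family = max(ivs, key=lambda t: (t[1] - t[0], [-ord(c) for c in t[2]]))[2]
    covered, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
    for s, e, _ in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / (end - start), best_family


def vntr_context(chrom: str, start: int, end: int, vntr: pd.DataFrame,
                 params: MechanismParams | None = None,
                 ) -> Tuple[bool, int | None]:
    """True iff both breakpoints sit in one tandem array and the event
    length is an integer multiple of its period within tolerance."""
    params = params or MechanismParams()
    if start >= end:
        raise InputError("vntr_context: empty interval")
    sub = vntr[(vntr["chrom"] == chrom)
               & (vntr["start"] <= start) & (vntr["end"] >= end)]
    length = end - start
    for row in sub.itertuples(index=False):
        p = int(row.period)
        if length < p:
            continue
        r = length % p
        if min(r, p - r) <= params.vntr_period_tolerance * p:
            return True, p
    return False, None


def classify_mechanism(event_id: str, chrom: str, start: int, end: int,
                       precise: bool, genome: Genome,
                       te: pd.DataFrame, vntr: pd.DataFrame,
                       params: MechanismParams | None = None) -> MechanismCall:
    """Assign one mechanism per event by signature precedence."""
    params = params or MechanismParams()
    if not precise:
        return MechanismCall(event_id, "ambiguous", reason="imprecise_breakpoints")
    seq = genome[chrom]
    if not (0 <= start < end <= len(seq)):
        return MechanismCall(event_id, "ambiguous", reason="out_of_bounds")
    body = _norm(seq[start:end])
    if np.mean(body == _N) > 0.5:
        return MechanismCall(event_id, "ambiguous", reason="n_rich_window")

    left, right, mh_total = junction_microhomology(
        seq, start, end, cap=params.homology_scan_window)
    hom_len, hom_id = flanking_homology(seq, start, end, params)
    te_frac, te_family = te_coverage(chrom, start, end, te)
    is_vntr, period = vntr_context(chrom, start, end, vntr, params)

    call = MechanismCall(
        event_id=event_id, mechanism="ambiguous",
        microhomology_len=mh_total, homology_len=hom_len,
        homology_identity=hom_id, te_fraction=te_frac,
        te_family=te_family, vntr_period=period)
    if is_vntr:
        call.mechanism = "VNTR"
    elif te_frac >= params.mei_min_fraction:
        call.mechanism = "MEI"
    elif hom_len >= params.nahr_min_len and hom_id >= params.nahr_min_identity:
        call.mechanism = "NAHR"
    elif mh_total <= params.mh_max:
        call.mechanism = "NHR"
        call.nhr_subtype = "NHEJ" if mh_total == 0 else "MMEJ"
    else:
        call.reason = "homology_between_nhr_and_nahr"
    return call


def classify_all(events, genome: Genome, te: pd.DataFrame,
                 vntr: pd.DataFrame,
                 params: MechanismParams | None = None) -> List[MechanismCall]:
    """Classify a list of ConsensusCnv/PolarizedCnv-like events."""
    params = params or MechanismParams()
    out = []
    for ev in events:
        call = classify_mechanism(ev.event_id, ev.chrom, ev.start, ev.end,
                                  ev.precise, genome, te, vntr, params)
        ev.mechanism = call.mechanism
        out.append(call)
    return out


def calls_to_frame(calls: Sequence[MechanismCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": c.event_id, "mechanism": c.mechanism,
        "microhomology_len": c.microhomology_len,
        "homology_len": c.homology_len,
        "homology_identity": round(c.homology_identity, 4),
        "te_fraction": round(c.te_fraction, 4),
        "te_family": c.te_family,
        "vntr_period": "" if c.vntr_period is None else c.vntr_period,
        "nhr_subtype": c.nhr_subtype, "reason": c.reason,
    } for c in calls], columns=["event_id", "mechanism", "microhomology_len",
                                "homology_len", "homology_identity",
                                "te_fraction", "te_family", "vntr_period",
                                "nhr_subtype", "reason"])


def summarize_mechanisms(calls: Sequence[MechanismCall],
                         events) -> Dict[str, pd.DataFrame]:
    """Count/percentage/cumulative-bp table plus per-chromosome counts."""
    ids = [c.event_id for c in calls]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate event_ids: {dupes}")
    ev_by_id = {e.event_id: e for e in events}
    rows = []
    for c in calls:
        e = ev_by_id[c.event_id]
        rows.append({"event_id": c.event_id, "mechanism": c.mechanism,
                     "chrom": e.chrom, "length": e.end - e.start})
    df = pd.DataFrame(rows)
    if df.empty:
        dist = pd.DataFrame(columns=["mechanism", "count", "percent",
                                     "cumulative_bp", "size_mean",
                                     "size_median", "size_min", "size_max"])
        return {"distribution": dist,
                "per_chromosome": pd.DataFrame(columns=["chrom", "mechanism", "count"])}
    g = df.groupby("mechanism")["length"]
    dist = pd.DataFrame({
        "count": g.size(), "cumulative_bp": g.sum(), "size_mean": g.mean(),
        "size_median": g.median(), "size_min": g.min(), "size_max": g.max(),
    }).reset_index()
    dist.insert(2, "percent", 100.0 * dist["count"] / dist["count"].sum())
    per_chrom = (df.groupby(["chrom", "mechanism"]).size()
                 .rename("count").reset_index())
    assert int(dist["count"].sum()) == len(calls)
    return {"distribution": dist, "per_chromosome": per_chrom}
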