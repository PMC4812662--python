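"""Consensus merging: reciprocal overlap, clustering, refinement, gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvpol.config import MergeParams
from cnvpol.merge import (CnvCall, InputError, cluster_by_reciprocal_overlap,
                          consensus_per_accession, merge_callsets,
                          reciprocal_overlap, refine_breakpoints)
from oracles import brute_force_clusters


def _call(start, end, caller="PE", acc="accA", chrom="chr1"):
    return CnvCall(chrom=chrom, start=start, end=end, caller=caller,
                   accession=acc, precise=caller == "SR")


@pytest.mark.parametrize("a,b,expected", [
    ((100, 200), (100, 200), 1.0),
    ((0, 100), (50, 250), 0.25),
    ((0, 100), (200, 300), 0.0),
    ((0, 100), (100, 200), 0.0),  # touching half-open intervals
])
def test_reciprocal_overlap_values(a, b, expected):
    assert reciprocal_overlap(a, b) == pytest.approx(expected)
    assert reciprocal_overlap(b, a) == pytest.approx(expected)


def test_reciprocal_overlap_rejects_empty_interval():
    with pytest.raises(InputError):
        reciprocal_overlap((10, 10), (0, 5))


@settings(max_examples=200, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 5_000),
       st.integers(0, 10_000), st.integers(1, 5_000))
def test_reciprocal_overlap_symmetric_and_bounded(a0, alen, b0, blen):
    a, b = (a0, a0 + alen), (b0, b0 + blen)
    ro = reciprocal_overlap(a, b)
    assert 0.0 <= ro <= 1.0
    assert ro == reciprocal_overlap(b, a)
    if a == b:
        assert ro == 1.0


def test_consensus_three_callers_cluster():
    calls = [_call(1000, 2000, "PE"), _call(1005, 1998, "SR"),
             _call(900, 2100, "RD")]
    out = consensus_per_accession(calls, MergeParams())
    assert len(out) == 1
    assert out[0].callers == {"PE", "SR", "RD"}
    assert (out[0].start, out[0].end, out[0].precise) == (1005, 1998, True)


def test_single_method_call_discarded():
    out = consensus_per_accession([_call(1000, 2000, "PE")], MergeParams())
    assert out == []


def test_disjoint_single_caller_clusters_discarded():
    calls = [_call(0, 100, "PE"), _call(1000, 1100, "SR")]
    assert consensus_per_accession(calls, MergeParams()) == []


def test_mixed_accessions_rejected():
    calls = [_call(0, 100, acc="accA"), _call(0, 100, acc="accB")]
    with pytest.raises(InputError, match="accession"):
        consensus_per_accession(calls, MergeParams())


def test_refine_modal_sr_wins():
    cluster = [_call(1005, 1998, "SR"), _call(1005, 1998, "SR"),
               _call(990, 2010, "PE")]
    assert refine_breakpoints(cluster) == (1005, 1998, True)


def test_refine_rd_only_is_imprecise():
    assert refine_breakpoints([_call(900, 2100, "RD")]) == (900, 2100, False)


def test_refine_pe_lower_median():
    cluster = [_call(100, 220, "PE"), _call(104, 200, "PE"),
               _call(90, 210, "PE"), _call(96, 190, "PE")]
    start, end, precise = refine_breakpoints(cluster)
    assert (start, end, precise) == (96, 200, True)


def test_refine_empty_cluster_rejected():
    with pytest.raises(InputError):
        refine_breakpoints([])


def test_population_merge_thresholds():
    """Identical call in 3 accessions kept; in only 2 accessions dropped."""
    def acc_calls(accs):
        calls = []
        for acc in accs:
            calls += [_call(5000, 6000, "PE", acc), _call(5000, 6000, "SR", acc)]
        return calls

    kept = merge_callsets(acc_calls(["a", "b", "c"]))
    assert len(kept) == 1
    assert kept[0].n_accessions == 3
    assert kept[0].carrier_accessions == {"a", "b", "c"}
    dropped = merge_callsets(acc_calls(["a", "b"]))
    assert dropped == []


@pytest.mark.parametrize("seed", range(20))
def test_clustering_matches_bruteforce_oracle(seed):
    """Interval-tree single linkage == all-pairs transitive closure,
    200 random intervals per seed."""
    rng = np.random.default_rng(seed)
    intervals = []
    for _ in range(200):
        chrom = f"chr{rng.integers(1, 3)}"
        s = int(rng.integers(0, 50_000))
        length = int(rng.integers(50, 5_000))
        intervals.append((chrom, s, s + length))
    got = sorted(cluster_by_reciprocal_overlap(intervals, 0.5))
    assert got == brute_force_clusters(intervals, 0.5)


def test_clustering_order_invariant():
    rng = np.random.default_rng(42)
    intervals = [("chr1", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 20_000, 100),
                                 rng.integers(50, 3_000, 100))]
    def canon(ivs):
        return sorted(tuple(sorted(ivs[i] for i in cl))
                      for cl in cluster_by_reciprocal_overlap(ivs, 0.5))

    base = canon(intervals)
    for perm_seed in range(3):
        order = np.random.default_rng(perm_seed).permutation(len(intervals))
        assert canon([intervals[i] for i in order]) == base


def test_merged_events_satisfy_both_gates(noisy_events):
    params = MergeParams()
    for ev in noisy_events:
        assert ev.n_accessions >= params.min_accessions
        assert len(ev.carrier_accessions) == ev.n_accessions
        assert any(len(cs) >= params.min_callers
                   for cs in ev.supporting_callers.values())


def test_noise_free_completeness(noise_free_sim, noise_free_events):
    """Perfect callers, no jitter: catalog == truth with exact breakpoints."""
    truth = {(t.chrom, t.ref_start, t.ref_end) for t in noise_free_sim.truth}
    got = {(e.chrom, e.start, e.end) for e in noise_free_events}
    assert got == truth


def test_representative_from_median_precise_member():
    """Across accessions the representative is the precise member with the
    median length (ties -> smallest start)."""
    calls = []
    for acc, (s, e) in zip("abc", [(100, 200), (102, 230), (98, 260)]):
        calls += [_call(s, e, "SR", acc), _call(s, e, "PE", acc)]
    ev = merge_callsets(calls)
    assert len(ev) == 1
    assert (ev[0].start, ev[0].end) == (102, 230)  # lengths 100,128,162
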