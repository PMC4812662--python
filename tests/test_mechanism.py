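"""Junction-signature primitives and the mechanism decision rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvpol.config import MechanismParams
from cnvpol.evaluate import match_to_truth, mechanism_accuracy
from cnvpol.io import seq_to_array
from cnvpol.mechanism import (InputError, MechanismCall, classify_all,
                              classify_mechanism, flanking_homology,
                              junction_microhomology, summarize_mechanisms,
                              te_coverage, vntr_context)
from oracles import bitmap_te_coverage, brute_force_microhomology


def test_microhomology_printed_example():
    seq = seq_to_array("TTACGTAAACGTCC")
    assert junction_microhomology(seq, 2, 8) == (0, 4, 4)


def test_microhomology_homopolymer_run():
    seq = seq_to_array("A" * 40)
    left, right, total = junction_microhomology(seq, 10, 20, cap=500)
    # run extends to the sequence end on the right, to the start on the left
    assert right == 20 and left == 10 and total == 30


def test_microhomology_blunt_junction():
    seq = seq_to_array("AAAATTTTGGGG")
    assert junction_microhomology(seq, 4, 8) == (0, 0, 0)


def test_microhomology_n_never_matches():
    seq = seq_to_array("ACGTNNACGTNNACGT")
    left, right, total = junction_microhomology(seq, 0, 6)
    assert right == 4 and total == 4  # stops at N even though N==N


def test_microhomology_out_of_bounds():
    with pytest.raises(InputError):
        junction_microhomology(seq_to_array("ACGT"), 2, 10)


@settings(max_examples=300, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_microhomology_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 400))
    seq = "".join(rng.choice(list("ACGTN"), size=n, p=[.24, .24, .24, .24, .04]))
    start = int(rng.integers(1, n - 10))
    end = int(rng.integers(start + 1, n))
    arr = seq_to_array(seq)
    assert junction_microhomology(arr, start, end) == \
        brute_force_microhomology(seq, start, end)


def test_flanking_homology_nahr_construction():
    rng = np.random.default_rng(0)
    bg = "".join(rng.choice(list("ACGT"), size=3000))
    rep = "".join(rng.choice(list("ACGT"), size=120))
    # deletion [1000,2000) between two repeat copies: one starts at the
    # event start, the other right at the event end
    seq = bg[:1000] + rep + bg[1120:2000] + rep + bg[2120:]
    arr = seq_to_array(seq)
    hom, ident = flanking_homology(arr, 1000, 2000)
    assert hom >= 120
    assert ident == pytest.approx(1.0, abs=0.02)


def test_flanking_homology_null_rate():
    """Random junctions essentially never show >= 10 bp of 90% homology."""
    rng = np.random.default_rng(7)
    hits = 0
    for _ in range(1000):
        seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=800)
        s = int(rng.integers(100, 300))
        e = int(rng.integers(s + 50, 700))
        hom, _ = flanking_homology(seq, s, e)
        hits += hom <= 10
    assert hits >= 990


def _te(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


def test_te_coverage_exact_and_half():
    te = _te([("chr1", 100, 200, "Gypsy1"), ("chr1", 500, 600, "Copia1")])
    assert te_coverage("chr1", 100, 200, te) == (1.0, "Gypsy1")
    frac, fam = te_coverage("chr1", 450, 650, te)
    assert frac == pytest.approx(0.5)
    assert fam == "Copia1"


def test_te_coverage_tie_breaks_lexicographic():
    te = _te([("chr1", 0, 100, "Zeta"), ("chr1", 100, 200, "Alpha")])
    frac, fam = te_coverage("chr1", 0, 200, te)
    assert frac == 1.0 and fam == "Alpha"


def test_te_coverage_matches_bitmap_oracle(noise_free_sim):
    sim = noise_free_sim
    rng = np.random.default_rng(5)
    for _ in range(100):
        chrom = f"chr{rng.integers(1, 3)}"
        s = int(rng.integers(0, 990_000))
        e = s + int(rng.integers(100, 10_000))
        frac, _ = te_coverage(chrom, s, e, sim.pack.te)
        assert frac == pytest.approx(
            bitmap_te_coverage(chrom, s, e, sim.pack.te), abs=1e-12)


def _vntr(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "period"])


def test_vntr_integer_multiple_rule():
    arrays = _vntr([("chr1", 1000, 1300, 15)])
    assert vntr_context("chr1", 1100, 1145, arrays) == (True, 15)   # 3 x 15
    assert vntr_context("chr1", 1100, 1140, arrays) == (False, None)  # 40/15


def test_vntr_requires_single_array():
    arrays = _vntr([("chr1", 0, 100, 10), ("chr1", 500, 600, 10)])
    assert vntr_context("chr1", 50, 550, arrays) == (False, None)


def test_classify_precedence_and_gap_band(noise_free_sim):
    sim = noise_free_sim
    genome = sim.pack.genome
    # VNTR beats MEI when both signatures hold
    vntr_truth = next(t for t in sim.truth if t.mechanism == "VNTR")
    fake_te = _te([(vntr_truth.chrom, vntr_truth.ref_start,
                    vntr_truth.ref_end, "Gypsy1")])
    call = classify_mechanism("x", vntr_truth.chrom, vntr_truth.ref_start,
                              vntr_truth.ref_end, True, genome, fake_te,
                              sim.pack.vntr)
    assert call.mechanism == "VNTR"
    # imprecise events are never classified
    call = classify_mechanism("y", "chr1", 1000, 2000, False, genome,
                              sim.pack.te, sim.pack.vntr)
    assert call.mechanism == "ambiguous" and call.reason


def test_homology_between_nhr_and_nahr_is_ambiguous():
    """25 bp of exact junction homology with no TE/array context falls in
    the gap between the NHR and NAHR definitions."""
    rng = np.random.default_rng(9)
    bg = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=4000)
    s, e = 1000, 2000
    bg[e:e + 25] = bg[s:s + 25]
    if bg[e + 25] == bg[s + 25]:
        bg[e + 25] = next(b for b in b"ACGT" if b != bg[s + 25])
    if bg[e - 1] == bg[s - 1]:
        bg[e - 1] = next(b for b in b"ACGT" if b != bg[s - 1])
    call = classify_mechanism("z", "chr1", s, e, True, {"chr1": bg},
                              _te([]), _vntr([]))
    assert call.microhomology_len == 25
    assert call.mechanism == "ambiguous"


def test_mei_threshold_monotonicity(noise_free_sim, noise_free_events):
    """Raising mei_min_fraction never increases the MEI count."""
    sim = noise_free_sim
    counts = []
    for frac in (0.6, 0.8, 0.95):
        calls = classify_all(noise_free_events, sim.pack.genome, sim.pack.te,
                             sim.pack.vntr,
                             MechanismParams(mei_min_fraction=frac))
        counts.append(sum(c.mechanism == "MEI" for c in calls))
    assert counts == sorted(counts, reverse=True)


def test_noise_free_mechanism_recovery(noise_free_sim, noise_free_events):
    """>= 95% overall and >= 90% per class on the default noise-free run."""
    sim = noise_free_sim
    calls = classify_all(noise_free_events, sim.pack.genome, sim.pack.te,
                         sim.pack.vntr)
    m = match_to_truth(noise_free_events, sim.truth)
    acc = mechanism_accuracy(calls, sim.truth, m.pairs)
    assert acc["accuracy"] >= 0.95
    assert all(v >= 0.90 for v in acc["per_class"].values())


def test_summarize_counts_and_recount_oracle(noise_free_sim, noise_free_events):
    sim = noise_free_sim
    calls = classify_all(noise_free_events, sim.pack.genome, sim.pack.te,
                         sim.pack.vntr)
    summary = summarize_mechanisms(calls, noise_free_events)
    dist = summary["distribution"]
    assert int(dist["count"].sum()) == len(calls)
    assert dist["percent"].sum() == pytest.approx(100.0)
    # independent recount by grouping the calls table
    recount = pd.Series([c.mechanism for c in calls]).value_counts()
    for r in dist.itertuples(index=False):
        assert recount[r.mechanism] == r.count
    per_chrom = summary["per_chromosome"]
    assert int(per_chrom["count"].sum()) == len(calls)


def test_summarize_empty_and_duplicates():
    assert summarize_mechanisms([], [])["distribution"].empty
    calls = [MechanismCall("a", "NHR"), MechanismCall("a", "NHR")]
    with pytest.raises(InputError, match="duplicate"):
        summarize_mechanisms(calls, [])
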