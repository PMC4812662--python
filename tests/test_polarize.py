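"""Synteny blocks, projection, and ancestral-state classification."""

import numpy as np
import pytest

from cnvpol.config import PolarizeParams, SimConfig, uniform_sensitivity
from cnvpol.evaluate import match_to_truth
from cnvpol.merge import calls_from_frame, merge_callsets
from cnvpol.polarize import (InputError, SyntenyAnchor, anchors_from_frame,
                             build_blocks, polarize_events,
                             project_to_outgroup)
from cnvpol.sim import simulate_all


def _anchor(i, ref_mid, out_mid, ref_chrom="chr1", out_chrom="chr1",
            strand="+", half=500):
    return SyntenyAnchor(f"g{i}", ref_chrom, ref_mid - half, ref_mid + half,
                         out_chrom, out_mid - half, out_mid + half, strand)


def test_collinear_anchors_form_one_block():
    anchors = [_anchor(i, 10_000 * (i + 1), 10_000 * (i + 1) + 2_000)
               for i in range(10)]
    blocks = build_blocks(anchors)
    assert len(blocks) == 1
    assert len(blocks[0].anchors) == 10


def test_chromosome_switch_splits_blocks():
    anchors = [_anchor(i, 10_000 * (i + 1), 10_000 * (i + 1)) for i in range(10)]
    anchors[5] = _anchor(5, 60_000, 60_000, out_chrom="chr9")
    blocks = build_blocks(anchors)
    # chain oracle: runs of consecutive compatible anchors -> 5, [1], 4
    assert [len(b.anchors) for b in blocks] == [5, 4]


def test_empty_anchor_list():
    assert build_blocks([]) == []


def test_duplicate_gene_id_rejected():
    anchors = [_anchor(0, 1000, 1000), _anchor(0, 5000, 5000)]
    with pytest.raises(InputError, match="duplicate"):
        build_blocks(anchors)


def test_projection_linear_interpolation():
    """Anchors 10k->12k and 20k->23k: [14k,16k) maps to [16.4k,18.6k)."""
    anchors = [_anchor(0, 10_000, 12_000), _anchor(1, 20_000, 23_000)]
    blocks = build_blocks(anchors)
    proj = project_to_outgroup("chr1", 14_000, 16_000, blocks)
    assert proj is not None
    assert (proj.start, proj.end) == (16_400, 18_600)


def test_projection_fails_off_anchored_chromosome():
    anchors = [_anchor(0, 10_000, 12_000), _anchor(1, 20_000, 23_000)]
    blocks = build_blocks(anchors)
    assert project_to_outgroup("chr7", 14_000, 16_000, blocks) is None


def test_projection_contains_true_locus(noise_free_sim):
    """At divergence 0 the projected window of random intervals contains
    the orthologous sequence (simulator coordinate truth)."""
    sim = noise_free_sim
    blocks = build_blocks(anchors_from_frame(sim.out.anchors))
    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(50):
        chrom = "chr1"
        m = sim.out.maps[chrom]
        s = int(rng.integers(5_000, 990_000))
        e = s + 1_000
        proj = project_to_outgroup(chrom, s, e, blocks)
        if proj is None:
            continue
        true_s, true_e = m.ref_to_out(s), m.ref_to_out(e)
        margin = proj.margin + 50
        assert proj.start - margin <= true_s
        assert proj.end + margin >= true_e
        checked += 1
    assert checked >= 40


def test_noise_free_polarity_recovery(noise_free_sim, noise_free_events,
                                      noise_free_polarized):
    """Divergence 0, no gaps: every event polarized to its true state."""
    m = match_to_truth(noise_free_events, noise_free_sim.truth)
    truth = {t.event_id: t for t in noise_free_sim.truth}
    pol = {p.event_id: p for p in noise_free_polarized}
    assert len(m.pairs) == len(noise_free_sim.truth)
    for tid, eid in m.pairs.items():
        assert pol[eid].ancestral_state == truth[tid].ancestral_state


def test_trichotomy(noisy_polarized):
    for p in noisy_polarized:
        assert p.ancestral_state in {"insertion", "deletion", "undefined"}


def test_gap_rate_monotonicity():
    """More assembly gaps never decrease the undefined count (fixed events
    and seed)."""
    undefined = []
    for gap_rate in (0.0, 2.0, 6.0):
        cfg = SimConfig(seed=31, outgroup_gap_rate=gap_rate,
                        events_per_mechanism={"NHR": 30, "MEI": 30},
                        caller_sensitivity=uniform_sensitivity(1.0),
                        breakpoint_jitter_sd={"PE": 0, "SR": 0, "RD": 0},
                        false_call_rate=0.0, rd_bin_size=1)
        sim = simulate_all(cfg)
        events = merge_callsets(calls_from_frame(sim.calls))
        pols = polarize_events(events, sim.pack.genome, sim.out.outgroup,
                               sim.out.gaps,
                               anchors_from_frame(sim.out.anchors))
        undefined.append(
            sum(p.ancestral_state == "undefined" for p in pols))
    assert undefined == sorted(undefined)


def test_flank_truncated_at_chromosome_start(noise_free_sim):
    """An event close to the contig edge still gets a verdict (flanks are
    truncated, not fatal)."""
    sim = noise_free_sim
    t = min(sim.truth, key=lambda t: t.ref_start)
    blocks_anchors = anchors_from_frame(sim.out.anchors)

    class Ev:
        event_id, chrom = "e", t.chrom
        start, end = t.ref_start, t.ref_end
        precise = True
        carrier_accessions = set()

    pols = polarize_events([Ev()], sim.pack.genome, sim.out.outgroup,
                           sim.out.gaps, blocks_anchors,
                           PolarizeParams(flank=2 * t.ref_start + 4000))
    assert pols[0].ancestral_state in {"insertion", "deletion", "undefined"}
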