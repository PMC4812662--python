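"""Simulator contracts: determinism, composition, and signature round trips."""

import numpy as np
import pandas as pd
import pytest

from cnvpol.config import ConfigError, SimConfig, uniform_sensitivity
from cnvpol.io import array_to_seq
from cnvpol.mechanism import junction_microhomology, te_coverage, flanking_homology
from cnvpol.sim import (emit_callsets, implant_events, mutate_outgroup,
                        noise_free_config, simulate_all, simulate_reference,
                        write_outputs)
from oracles import brute_force_microhomology

import edlib


@pytest.mark.parametrize("field,value", [
    ("chrom_length", 10_000),
    ("gc_content", 1.5),
    ("outgroup_divergence", 0.5),
    ("insertion_fraction", -0.1),
    ("n_chromosomes", 0),
])
def test_invalid_config_names_field(field, value):
    with pytest.raises(ConfigError, match=field):
        SimConfig(**{field: value})


def test_reference_shape_and_determinism(tiny_config):
    cfg = SimConfig(**tiny_config)
    pack1 = simulate_reference(cfg)
    pack2 = simulate_reference(SimConfig(**tiny_config))
    assert set(pack1.genome) == {"chr1", "chr2"}
    assert all(len(s) == cfg.chrom_length for s in pack1.genome.values())
    for c in pack1.genome:
        assert np.array_equal(pack1.genome[c], pack2.genome[c])
    assert pack1.te.equals(pack2.te)
    assert pack1.vntr.equals(pack2.vntr)


def test_written_outputs_are_byte_identical(tiny_config, tmp_path):
    import hashlib, os

    def digest(d):
        out = {}
        for root, _, files in os.walk(d):
            for f in sorted(files):
                if f.endswith(".fai"):
                    continue
                p = os.path.join(root, f)
                out[os.path.relpath(p, d)] = hashlib.md5(
                    open(p, "rb").read()).hexdigest()
        return out

    a, b = tmp_path / "a", tmp_path / "b"
    write_outputs(simulate_all(SimConfig(**tiny_config)), str(a))
    write_outputs(simulate_all(SimConfig(**tiny_config)), str(b))
    assert digest(a) == digest(b)


def test_background_gc_content(noise_free_sim):
    """Non-feature background GC lands within 0.44 +/- 0.01."""
    sim = noise_free_sim
    gc_bases = frozenset(b"GC")
    total = gc = 0
    for chrom, seq in sim.pack.genome.items():
        mask = np.ones(len(seq), dtype=bool)
        for df in (sim.pack.te, sim.pack.vntr):
            for r in df[df["chrom"] == chrom].itertuples(index=False):
                mask[max(0, r.start - 400):r.end + 400] = False
        for t in sim.truth:
            if t.chrom == chrom:
                mask[max(0, t.ref_start - 400):t.ref_end + 400] = False
        bg = seq[mask]
        total += len(bg)
        gc += int(np.isin(bg, np.frombuffer(b"GC", dtype=np.uint8)).sum())
    assert total > 500_000
    assert abs(gc / total - 0.44) < 0.01


def test_te_copies_match_library(noise_free_sim):
    """Every annotated TE interval is >= 80% identical to its consensus."""
    sim = noise_free_sim
    for r in sim.pack.te.sample(30, random_state=0).itertuples(index=False):
        copy = array_to_seq(sim.pack.genome[r.chrom][r.start:r.end])
        cons = array_to_seq(sim.pack.te_library[r.family])
        res = edlib.align(copy, cons, mode="HW", task="distance")
        assert res["editDistance"] / len(copy) <= 0.2, r


def test_vntr_annotations_are_tandem(noise_free_sim):
    sim = noise_free_sim
    for r in sim.pack.vntr.itertuples(index=False):
        p = int(r.period)
        assert 2 <= p <= 100
        n = (r.end - r.start) // p
        assert n >= 3
        arr = sim.pack.genome[r.chrom][r.start:r.end]
        # unit repeats exactly (arrays are written as exact tandem copies)
        assert np.array_equal(arr[:p], arr[p:2 * p])


def test_gene_models_are_valid(noise_free_sim):
    for g in noise_free_sim.pack.genes:
        g.validate()  # exon overlap / CDS-in-exon contracts


def test_event_counts_and_polarity_assignment():
    cfg = noise_free_config(
        seed=5, events_per_mechanism={"NHR": 10}, insertion_fraction=0.0,
        n_chromosomes=2, chrom_length=200_000, n_genes=10, n_te_copies=5,
        n_vntr_arrays=2)
    pack = simulate_reference(cfg)
    truth = implant_events(pack, cfg)
    assert len(truth) == 10
    assert all(t.mechanism == "NHR" for t in truth)
    assert all(t.ancestral_state == "deletion" for t in truth)
    assert all(t.carrier_accessions for t in truth)
    assert all(t.ref_end - t.ref_start >= 50 for t in truth)


def test_signature_round_trips(noise_free_sim):
    """Implanted signatures are recoverable by the junction primitives."""
    sim = noise_free_sim
    for t in sim.truth:
        seq = sim.pack.genome[t.chrom]
        if t.mechanism == "MEI":
            frac, fam = te_coverage(t.chrom, t.ref_start, t.ref_end, sim.pack.te)
            assert frac >= 0.9
            assert fam == t.te_family
        elif t.mechanism == "NHR":
            oracle = brute_force_microhomology(
                array_to_seq(seq), t.ref_start, t.ref_end)
            assert oracle[2] <= 10
            assert junction_microhomology(
                seq, t.ref_start, t.ref_end)[2] == oracle[2]
        elif t.mechanism == "NAHR":
            hom, ident = flanking_homology(seq, t.ref_start, t.ref_end)
            assert hom >= 100 and ident >= 0.9


def test_outgroup_identity_at_zero_divergence(noise_free_sim):
    """divergence 0, no indels: outgroup equals the ancestral haplotype;
    insertion events are absent from it, deletions present."""
    sim = noise_free_sim
    for chrom in sim.pack.genome:
        assert np.array_equal(sim.out.outgroup[chrom], sim.out.ancestral[chrom])
    out_str = {c: array_to_seq(s) for c, s in sim.out.outgroup.items()}
    rng = np.random.default_rng(0)
    for t in rng.choice(sim.truth, size=40, replace=False):
        body = array_to_seq(
            sim.pack.genome[t.chrom][t.ref_start:t.ref_end])
        if t.ancestral_state == "deletion":
            assert body in out_str[t.chrom]
        elif t.mechanism in ("NHR", "NAHR") and t.ref_end - t.ref_start > 200:
            # unique sequence: absent from the whole outgroup chromosome
            probe = body[50:250]
            assert probe not in out_str[t.chrom]


def test_outgroup_divergence_level():
    """At 2% substitution divergence, sampled 1-kb orthologous windows show
    mean identity 0.98 +/- 0.005."""
    cfg = noise_free_config(seed=8, outgroup_divergence=0.02,
                            events_per_mechanism={"NHR": 5},
                            chrom_length=200_000, n_genes=10, n_te_copies=5,
                            n_vntr_arrays=2)
    pack = simulate_reference(cfg)
    truth = implant_events(pack, cfg)
    out = mutate_outgroup(pack, truth, cfg)
    rng = np.random.default_rng(1)
    idents = []
    for _ in range(10):
        chrom = "chr1"
        s = int(rng.integers(0, len(out.ancestral[chrom]) - 1000))
        a = out.ancestral[chrom][s:s + 1000]
        b = out.outgroup[chrom][s:s + 1000]
        idents.append(float(np.mean(a == b)))
    assert abs(np.mean(idents) - 0.98) < 0.005


def test_emit_callsets_noise_free_limit(noise_free_sim):
    sim = noise_free_sim
    expected = sum(3 * len(t.carrier_accessions) for t in sim.truth)
    assert len(sim.calls) == expected
    by_id = {(t.chrom, t.ref_start, t.ref_end) for t in sim.truth}
    for r in sim.calls.itertuples(index=False):
        assert (r.chrom, r.start, r.end) in by_id  # exact breakpoints


def test_emit_callsets_zero_sensitivity(tiny_config):
    cfg = SimConfig(**{**tiny_config,
                       "caller_sensitivity": uniform_sensitivity(0.0),
                       "false_call_rate": 0.0})
    pack = simulate_reference(cfg)
    truth = implant_events(pack, cfg)
    assert emit_callsets(truth, cfg).empty


def test_emit_callsets_binomial_count():
    """~200 truth-carrier-caller triples at sensitivity 0.9: emitted count
    inside the binomial 99% interval 180 +/- 17."""
    cfg = SimConfig(n_chromosomes=2, chrom_length=300_000,
                    events_per_mechanism={"NHR": 16}, n_accessions=5,
                    n_genes=10, n_te_copies=5, n_vntr_arrays=2,
                    caller_sensitivity=uniform_sensitivity(0.9),
                    false_call_rate=0.0, seed=21)
    pack = simulate_reference(cfg)
    truth = implant_events(pack, cfg)
    triples = sum(3 * len(t.carrier_accessions) for t in truth)
    calls = emit_callsets(truth, cfg)
    lo, hi = 0.9 * triples - 2.58 * np.sqrt(triples * 0.09), \
        0.9 * triples + 2.58 * np.sqrt(triples * 0.09)
    assert lo <= len(calls) <= hi


def test_truth_conservation(noise_free_sim):
    counts = pd.Series([t.mechanism for t in noise_free_sim.truth]).value_counts()
    assert counts.to_dict() == {"MEI": 50, "VNTR": 50, "NAHR": 50, "NHR": 50}
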