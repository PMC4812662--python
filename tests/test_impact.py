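"""Gene impact categories, population sharing, and term enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cnvpol.impact import (GeneModel, InputError,
                           classify_gene_impact, hypergeom_enrichment,
                           population_sharing, sharing_fractions)
from oracles import bitmap_gene_category


def _gene(gene_id="g1", chrom="chr1", start=1000, end=3000):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand="+",
        exons=[(start, start + 500), (end - 700, end)],
        cds=[(start + 200, start + 500), (end - 700, end - 300)],
        utr5=[(start, start + 200)], utr3=[(end - 300, end)])


class _Ev:
    def __init__(self, event_id, start, end, chrom="chr1", carriers=()):
        self.event_id = event_id
        self.chrom = chrom
        self.start = start
        self.end = end
        self.carrier_accessions = set(carriers)


def test_gene_model_validation_names_gene():
    g = _gene()
    g.cds.append((5000, 6000))  # outside gene span
    with pytest.raises(InputError, match="g1"):
        g.validate()


@pytest.mark.parametrize("interval,expected", [
    ((0, 5000), "full"),          # event contains the whole gene
    ((1300, 1400), "partial_cds"),
    ((1050, 1150), "utr_only"),
    ((1600, 1800), "intron_only"),
])
def test_impact_categories(interval, expected):
    records, _ = classify_gene_impact(
        [_Ev("e1", *interval)], [_gene()])
    assert len(records) == 1
    assert records[0].category == expected


def test_no_overlap_no_record():
    records, summary = classify_gene_impact([_Ev("e1", 9000, 9500)], [_gene()])
    assert records == [] and summary["genes_affected"] == 0


def test_summary_counts_distinct_genes():
    genes = [_gene("g1"), _gene("g2", start=10_000, end=12_000)]
    events = [_Ev("e1", 0, 5000), _Ev("e2", 500, 4000),
              _Ev("e3", 10_100, 10_300)]
    records, summary = classify_gene_impact(events, genes)
    assert len(records) == 3  # g1 hit twice, g2 once
    assert summary["genes_affected"] == 2
    assert summary["cnvs_hitting_genes"] == 3
    assert summary["full"] == 1  # g1 counted once at highest precedence
    assert summary["cds_disrupted_genes"] == summary["full"] + summary["partial_cds"]


def test_impact_matches_bitmap_oracle(noise_free_sim, noise_free_events):
    """Interval logic equals the per-base annotation oracle on the fixture."""
    sim = noise_free_sim
    records, _ = classify_gene_impact(noise_free_events, sim.pack.genes)
    genes = {g.gene_id: g for g in sim.pack.genes}
    events = {e.event_id: e for e in noise_free_events}
    assert records, "fixture must produce gene-event overlaps"
    for r in records:
        ev = events[r.event_id]
        assert r.category == bitmap_gene_category(
            (ev.start, ev.end), genes[r.gene_id])


def test_population_sharing_labels():
    groups = pd.DataFrame({
        "accession": ["a", "b", "c", "d"],
        "group": ["cultivated", "cultivated", "wild", "cultivated"],
        "subgroup": ["indica", "japonica", "other", "indica"]})
    events = [_Ev("e1", 0, 100, carriers={"a", "b", "c"}),
              _Ev("e2", 0, 100, carriers={"a", "b"}),
              _Ev("e3", 0, 100, carriers={"c"}),
              _Ev("e4", 0, 100, carriers={"a", "d"})]
    sharing = population_sharing(events, groups)
    assert list(sharing["cultivated_wild"]) == [
        "shared", "cultivated_only", "wild_only", "cultivated_only"]
    assert list(sharing["indica_japonica"]) == [
        "shared", "shared", "neither", "indica_only"]
    fracs = sharing_fractions(sharing)
    for part in fracs.values():
        assert sum(part.values()) == pytest.approx(1.0)


def test_population_sharing_unlabeled_accession():
    groups = pd.DataFrame({"accession": ["a"], "group": ["wild"],
                           "subgroup": ["other"]})
    with pytest.raises(InputError, match="zzz"):
        population_sharing([_Ev("e1", 0, 100, carriers={"zzz"})], groups)


def test_wild_only_fraction_is_rare(noisy_sim, noisy_events):
    """Carriers drawn uniformly from a 5:1 cultivated:wild panel make
    wild-only events rare (every carrier wild, p <= (2/12)^3)."""
    sharing = population_sharing(noisy_events, noisy_sim.groups)
    frac = (sharing["cultivated_wild"] == "wild_only").mean()
    assert frac <= 0.02


def test_hypergeom_exact_example():
    """N=10, K=4, n=5, k=4 -> 6/252, checked by exhaustive enumeration."""
    universe = {f"g{i}" for i in range(10)}
    term_genes = {f"g{i}" for i in range(4)}
    study = {"g0", "g1", "g2", "g3", "g9"}
    res = hypergeom_enrichment(study, {g: {"T"} for g in term_genes}, universe)
    assert len(res) == 1
    # enumeration oracle over all C(10,5) draws
    hits = sum(1 for draw in combinations(sorted(universe), 5)
               if len(set(draw) & term_genes) >= 4)
    assert res[0].p_value == pytest.approx(hits / 252)
    assert res[0].p_value == pytest.approx(6 / 252)


def test_hypergeom_k0_is_one():
    universe = {f"g{i}" for i in range(10)}
    res = hypergeom_enrichment({"g9"}, {"g0": {"T"}}, universe)
    assert res[0].k == 0
    assert res[0].p_value == pytest.approx(1.0)


def test_study_outside_universe_rejected():
    with pytest.raises(InputError, match="alien"):
        hypergeom_enrichment({"alien"}, {}, {"g1"})


def test_bh_fdr_is_stepup_monotone():
    rng = np.random.default_rng(12)
    universe = {f"g{i}" for i in range(300)}
    term_map = {}
    for t in range(25):
        for g in rng.choice(sorted(universe), size=30, replace=False):
            term_map.setdefault(g, set()).add(f"T{t}")
    study = set(rng.choice(sorted(universe), size=60, replace=False))
    res = hypergeom_enrichment(study, term_map, universe)
    ordered = sorted(res, key=lambda r: r.p_value)
    fdrs = [r.fdr for r in ordered]
    assert fdrs == sorted(fdrs)
    assert all(r.fdr >= r.p_value - 1e-12 for r in res)


def test_null_calibration():
    """Under uniform null draws, ~5% of term tests fall below p=0.05."""
    # design N=1000, K=250, n=250: discrete achievable level 0.047
    rng = np.random.default_rng(99)
    N, n_terms, n_study, draws = 1000, 20, 250, 1000
    universe = [f"g{i}" for i in range(N)]
    term_map = {}
    for t in range(n_terms):
        for g in rng.choice(universe, size=250, replace=False):
            term_map.setdefault(g, set()).add(f"T{t}")
    below = total = 0
    for _ in range(draws // 10):  # 100 draws x 20 terms = 2000 tests
        study = set(rng.choice(universe, size=n_study, replace=False))
        for r in hypergeom_enrichment(study, term_map, set(universe)):
            total += 1
            below += r.p_value < 0.05
    assert abs(below / total - 0.05) <= 0.02
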