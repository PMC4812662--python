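"""Reference-genome synthesis: background, TE copies, tandem arrays, genes.

The genome is a GC-matched i.i.d. background into which annotated features
are written: copies of a small transposable-element library (fragments at
80-100% identity to their consensus), tandem-repeat arrays (period 5-60 bp,
>= 4 copies), and intron/exon gene models. Feature intervals never overlap
each other; CNV events are implanted later (cnvpol.sim.events) and may
overlap genes but not TE/array features, so that junction signatures stay
attributable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ..config import SimConfig, uniform_sensitivity
from ..io import Genome
from ..impact import GeneModel

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TE_FAMILY_STEMS = ["Mutator_like", "Gypsy", "Copia", "hAT", "CACTA", "LINE"]
_TE_LENGTHS = [1800, 7000, 4500, 2500, 800, 400]


@dataclass
class GenomePack:
    """Reference genome plus its annotations and the TE library."""

    genome: Genome
    te: pd.DataFrame           # chrom, start, end, family
    vntr: pd.DataFrame         # chrom, start, end, period
    genes: List[GeneModel]
    te_library: Dict[str, np.ndarray]
    terms: pd.DataFrame        # gene_id, term_id
    config: SimConfig
    occupied: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def mutate_subs(rng: np.random.Generator, seq: np.ndarray,
                rate: float) -> np.ndarray:
    """Substitute each base with a different one with the given probability."""
    out = seq.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(seq)) < rate
    idx = np.searchsorted(BASES, out[mask])
    out[mask] = BASES[(idx + rng.integers(1, 4, size=mask.sum())) % 4]
    return out


def _place(rng: np.random.Generator, occupied: IntervalTree, chrom_len: int,
           size: int, pad: int, edge: int = 1000,
           max_tries: int = 1500) -> Optional[int]:
    """Random start for a [start,start+size) slot with ``pad`` clearance."""
    if chrom_len - size - 2 * edge <= 0:
        return None
    for _ in range(max_tries):
        s = int(rng.integers(edge, chrom_len - size - edge))
        if not occupied.overlap(s - pad, s + size + pad):
            occupied.addi(s, s + size)
            return s
    return None


def _make_gene(rng: np.random.Generator, chrom: str, start: int,
               length: int, gene_id: str) -> GeneModel:
    n_exons = int(rng.integers(2, 7))
    # split gene length into exon/intron alternation; exons >= 150 bp
    cuts = np.sort(rng.choice(
        np.arange(150, length - 150), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons: List[Tuple[int, int]] = []
    for i in range(0, len(bounds) - 1, 2):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if e - s >= 20:
            exons.append((start + s, start + e))
    strand = "+" if rng.random() < 0.5 else "-"
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    left_len = min(int(rng.integers(50, 200)), (first_e - first_s) // 2)
    right_len = min(int(rng.integers(50, 200)), (last_e - last_s) // 2)
    left_utr = (first_s, first_s + left_len)
    right_utr = (last_e - right_len, last_e)
    cds = []
    for i, (s, e) in enumerate(exons):
        cs, ce = s, e
        if i == 0:
            cs = left_utr[1]
        if i == len(exons) - 1:
            ce = right_utr[0]
        if ce > cs:
            cds.append((cs, ce))
    utr5 = [left_utr if strand == "+" else right_utr]
    utr3 = [right_utr if strand == "+" else left_utr]
    g = GeneModel(gene_id=gene_id, chrom=chrom, start=start,
                  end=start + length, strand=strand, exons=exons,
                  cds=cds, utr5=utr5, utr3=utr3)
    g.validate()
    return g


def simulate_reference(config: SimConfig) -> GenomePack:
    """Build the reference genome pack; deterministic for a fixed seed."""
    config.validate()
    rng = _rng(config, 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome: Genome = {
        c: random_seq(rng, config.chrom_length, config.gc_content)
        for c in chroms}
    occupied = {c: IntervalTree() for c in chroms}

    # TE library: fixed family stems, spread of consensus lengths
    te_library: Dict[str, np.ndarray] = {}
    for i in range(config.te_library_size):
        name = f"{_TE_FAMILY_STEMS[i % len(_TE_FAMILY_STEMS)]}{i // len(_TE_FAMILY_STEMS) + 1}"
        length = _TE_LENGTHS[i % len(_TE_LENGTHS)]
        te_library[name] = random_seq(rng, length, 0.5)

    te_rows = []
    families = sorted(te_library)
    for _ in range(config.n_te_copies):
        fam = families[int(rng.integers(len(families)))]
        cons = te_library[fam]
        if rng.random() < 0.5 or len(cons) <= 300:
            frag = cons
        else:  # truncated copy
            flen = int(rng.integers(200, len(cons)))
            off = int(rng.integers(0, len(cons) - flen + 1))
            frag = cons[off:off + flen]
        copy = mutate_subs(rng, frag, float(rng.uniform(0.0, 0.1)))
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = _place(rng, occupied[chrom], config.chrom_length, len(copy), pad=200)
        if s is None:
            continue
        genome[chrom][s:s + len(copy)] = copy
        te_rows.append((chrom, s, s + len(copy), fam))

    vntr_rows = []
    for _ in range(config.n_vntr_arrays):
        period = int(rng.integers(5, 61))
        copies = int(rng.integers(4, 13))
        unit = random_seq(rng, period, 0.5)
        arr = np.tile(unit, copies)
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = _place(rng, occupied[chrom], config.chrom_length, len(arr), pad=200)
        if s is None:
            continue
        genome[chrom][s:s + len(arr)] = arr
        vntr_rows.append((chrom, s, s + len(arr), period))

    genes: List[GeneModel] = []
    for i in range(config.n_genes):
        length = int(rng.integers(1000, 5001))
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = _place(rng, occupied[chrom], config.chrom_length, length, pad=200)
        if s is None:
            continue
        genes.append(_make_gene(rng, chrom, s, length, f"gene_{i + 1:04d}"))
    genes.sort(key=lambda g: (g.chrom, g.start))

    term_pool = [f"TERM:{i:04d}" for i in range(1, 31)]
    term_rows = []
    for g in genes:
        k = int(rng.integers(1, 5))
        for t in rng.choice(term_pool, size=k, replace=False):
            term_rows.append((g.gene_id, str(t)))

    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family"])
    vntr = pd.DataFrame(vntr_rows, columns=["chrom", "start", "end", "period"])
    terms = pd.DataFrame(term_rows, columns=["gene_id", "term_id"])
    return GenomePack(genome=genome, te=te, vntr=vntr, genes=genes,
                      te_library=te_library, terms=terms, config=config,
                      occupied=occupied)


def noise_free_config(**overrides) -> SimConfig:
    """The noise-free study conditions: perfect callers, identical outgroup.

    Sensitivities 1 everywhere, no jitter, no false calls, divergence 0,
    no outgroup indels, no assembly gaps.
    """
    base = dict(
        caller_sensitivity=uniform_sensitivity(1.0),
        breakpoint_jitter_sd={"PE": 0.0, "SR": 0.0, "RD": 0.0},
        false_call_rate=0.0,
        outgroup_divergence=0.0,
        outgroup_indel_rate=0.0,
        outgroup_gap_rate=0.0,
        rd_bin_size=1,
    )
    base.update(overrides)
    return SimConfig(**base)
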