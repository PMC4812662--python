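"""Implant mechanism-labelled CNV events into the reference genome.

Events are deletions relative to the reference: the event interval exists
on the reference and carrier accessions lack it. Each mechanism writes its
diagnostic signature into the reference sequence:

* MEI  — a TE-library copy with a 5-20 bp target-site duplication (the
  event spans one TSD copy plus the element; the second TSD copy sits just
  past the event end, so deleting the event restores a single target site);
* NAHR — a 100-300 bp repeat at >= 97% identity written at both junctions
  (deleting the event leaves one hybrid repeat);
* NHR  — a plain interval with an enforced junction microhomology of 0
  (NHEJ) or 1-10 bp (MMEJ);
* VNTR — an integer number of periods removed from a tandem array written
  and annotated on the fly.

Ancestral polarity (insertion in the reference lineage vs. bona fide
deletion) is assigned to an exact ``insertion_fraction`` of events. Events
are >= 1 kb apart, never overlap TE/tandem-array annotations (so junction
signatures stay attributable), but may overlap genes.

``implant_duplications`` additionally copies existing genes to new loci as
insertion-state events whose flanks carry a duplication-origin signature
(TE-flanked capture, NHEJ microhomology, or NAHR flanking homology); these
drive the non-co-linear gene origin analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ..config import SimConfig
from ..impact import GeneModel
from .reference import GenomePack, _place, _rng, mutate_subs, random_seq

SIZE_CLIP = (62, 30_000)
SIZE_MEDIAN = 1118.0   # catalog-scale median event size
SIZE_SIGMA = 1.62      # log-sd: mean/median ~ 3.7, ~90% of events < 10 kb


class PlacementError(RuntimeError):
    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"could only place {placed} of {requested} events")
        self.placed = placed


@dataclass
class TruthRecord:
    """Ground truth for one implanted event."""

    event_id: str
    chrom: str
    ref_start: int
    ref_end: int
    mechanism: str          # MEI | VNTR | NAHR | NHR
    ancestral_state: str    # insertion | deletion
    carrier_accessions: Set[str]
    te_family: str = ""
    microhomology_len: int = 0
    homology_len: int = 0
    vntr_period: Optional[int] = None
    gap_overlap_frac: float = 0.0
    origin: str = ""          # duplication implants only: TE | NHEJ | NAHR
    gene_id: str = ""         # duplicated gene copy id
    source_gene_id: str = ""

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


def truth_to_frame(truth: List[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "event_id": t.event_id, "chrom": t.chrom,
        "ref_start": t.ref_start, "ref_end": t.ref_end,
        "length": t.length, "mechanism": t.mechanism,
        "ancestral_state": t.ancestral_state,
        "carrier_accessions": ",".join(sorted(t.carrier_accessions)),
        "te_family": t.te_family,
        "microhomology_len": t.microhomology_len,
        "homology_len": t.homology_len,
        "vntr_period": "" if t.vntr_period is None else t.vntr_period,
        "gap_overlap_frac": round(t.gap_overlap_frac, 4),
        "origin": t.origin, "gene_id": t.gene_id,
        "source_gene_id": t.source_gene_id,
    } for t in truth])


def _draw_size(rng: np.random.Generator, lo: int = SIZE_CLIP[0],
               hi: int = SIZE_CLIP[1]) -> int:
    s = int(round(rng.lognormal(math.log(SIZE_MEDIAN), SIZE_SIGMA)))
    return int(min(max(s, lo), hi))


def _force_mismatch(genome, chrom: str, pos: int, other: int) -> None:
    """Make genome[chrom][pos] differ from genome[chrom][other]."""
    seq = genome[chrom]
    if pos >= len(seq) or other >= len(seq):
        return
    if seq[pos] == seq[other]:
        for b in b"ACGT":
            if b != seq[other]:
                seq[pos] = b
                break


def _blocked_tree(pack: GenomePack) -> Dict[str, IntervalTree]:
    """Feature intervals events must keep clear of (TEs and arrays)."""
    trees = {c: IntervalTree() for c in pack.genome}
    for df in (pack.te, pack.vntr):
        for row in df.itertuples(index=False):
            trees[row.chrom].addi(int(row.start), int(row.end))
    return trees


def _draw_carriers(rng: np.random.Generator, config: SimConfig) -> Set[str]:
    accs = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
    k_min = min(3, config.n_accessions)
    k = int(rng.integers(k_min, config.n_accessions + 1))
    return set(rng.choice(accs, size=k, replace=False).tolist())


def implant_events(pack: GenomePack,
                   config: SimConfig | None = None) -> List[TruthRecord]:
    """Write all requested events into pack.genome; return the truth set."""
    config = config or pack.config
    rng = _rng(config, 2)
    chroms = list(pack.genome)
    blocked = _blocked_tree(pack)
    families = sorted(pack.te_library)
    requested = [(mech, i)
                 for mech in sorted(config.events_per_mechanism)
                 for i in range(config.events_per_mechanism[mech])]
    n_total = len(requested)
    n_ins = int(round(config.insertion_fraction * n_total))
    states = np.array(["deletion"] * n_total, dtype=object)
    states[rng.permutation(n_total)[:n_ins]] = "insertion"

    # phase 1: draw every event's parameters, carriers and polarity up front
    specs = []
    for idx, (mech, _) in enumerate(requested):
        spec = {"mechanism": mech, "state": str(states[idx]),
                "carriers": _draw_carriers(rng, config)}
        if mech == "NHR":
            spec["size"] = _draw_size(rng)
            spec["mh"] = 0 if rng.random() < 0.4 else int(rng.integers(1, 11))
            spec["footprint"] = spec["size"] + 12
        elif mech == "MEI":
            fam = families[int(rng.integers(len(families)))]
            tsd = int(rng.integers(5, 21))
            spec.update(family=fam, tsd=tsd,
                        tsd_seq=random_seq(rng, tsd, 0.5),
                        body=mutate_subs(rng, pack.te_library[fam],
                                         float(rng.uniform(0.005, 0.02))))
            spec["size"] = tsd + len(spec["body"])
            spec["footprint"] = spec["size"] + tsd + 1
        elif mech == "NAHR":
            rep_len = int(rng.integers(100, 301))
            rep = random_seq(rng, rep_len, 0.5)
            spec.update(size=_draw_size(rng, lo=rep_len + 100), rep=rep,
                        rep2=mutate_subs(rng, rep, 0.02))
            spec["footprint"] = spec["size"] + rep_len
        else:  # VNTR
            period = int(rng.integers(10, 61))
            k_min = max(1, math.ceil(62 / period))
            k = int(rng.integers(k_min, k_min + 3))
            extra = int(rng.integers(3, 7))
            spec.update(period=period, k=k, extra=extra,
                        unit=random_seq(rng, period, 0.5),
                        offset=int(rng.integers(0, extra * period + 1)))
            spec["size"] = k * period
            spec["footprint"] = (k + extra) * period
        specs.append(spec)

    # phase 2: place and write, largest footprint first (avoids running out
    # of long contiguous free space on the fragmented chromosome)
    truth: List[TruthRecord] = []
    te_rows, vntr_rows = [], []
    order = sorted(range(len(specs)),
                   key=lambda i: (-specs[i]["footprint"], i))
    for idx in order:
        spec = specs[idx]
        first = int(rng.integers(len(chroms)))
        s = None
        for ci in range(len(chroms)):
            chrom = chroms[(first + ci) % len(chroms)]
            s = _place(rng, blocked[chrom], len(pack.genome[chrom]),
                       spec["footprint"], pad=1000)
            if s is not None:
                break
        if s is None:
            raise PlacementError(len(truth), n_total)
        seq = pack.genome[chrom]
        mech = spec["mechanism"]
        if mech == "NHR":
            e = s + spec["size"]
            mh = spec["mh"]
            if mh:
                seq[e:e + mh] = seq[s:s + mh]
            _force_mismatch(pack.genome, chrom, e + mh, s + mh)
            _force_mismatch(pack.genome, chrom, e - 1, s - 1)
            rec = TruthRecord("", chrom, s, e, "NHR", "", set(),
                              microhomology_len=mh)
        elif mech == "MEI":
            e = s + spec["size"]
            tsd = spec["tsd"]
            seq[s:s + tsd] = spec["tsd_seq"]
            seq[s + tsd:e] = spec["body"]
            seq[e:e + tsd] = spec["tsd_seq"]
            _force_mismatch(pack.genome, chrom, e + tsd, s + tsd)
            te_rows.append((chrom, s + tsd, e, spec["family"]))
            rec = TruthRecord("", chrom, s, e, "MEI", "", set(),
                              te_family=spec["family"],
                              microhomology_len=tsd)
        elif mech == "NAHR":
            e = s + spec["size"]
            rep_len = len(spec["rep"])
            seq[s:s + rep_len] = spec["rep"]
            seq[e:e + rep_len] = spec["rep2"]
            rec = TruthRecord("", chrom, s, e, "NAHR", "", set(),
                              homology_len=rep_len)
        else:  # VNTR
            period, k, extra = spec["period"], spec["k"], spec["extra"]
            arr_len = (k + extra) * period
            seq[s:s + arr_len] = np.tile(spec["unit"], k + extra)
            a = s
            s, e = a + spec["offset"], a + spec["offset"] + k * period
            vntr_rows.append((chrom, a, a + arr_len, period))
            rec = TruthRecord("", chrom, s, e, "VNTR", "", set(),
                              vntr_period=period)
        rec.ancestral_state = spec["state"]
        rec.carrier_accessions = spec["carriers"]
        truth.append(rec)

    if te_rows:
        pack.te = pd.concat(
            [pack.te, pd.DataFrame(te_rows, columns=pack.te.columns)],
            ignore_index=True)
    if vntr_rows:
        pack.vntr = pd.concat(
            [pack.vntr, pd.DataFrame(vntr_rows, columns=pack.vntr.columns)],
            ignore_index=True)
    pack.te = pack.te.sort_values(["chrom", "start"]).reset_index(drop=True)
    pack.vntr = pack.vntr.sort_values(["chrom", "start"]).reset_index(drop=True)
    truth.sort(key=lambda t: (t.chrom, t.ref_start))
    for i, t in enumerate(truth):
        t.event_id = f"ev_{i + 1:04d}"
    return truth


def implant_duplications(pack: GenomePack, truth: List[TruthRecord],
                         config: SimConfig | None = None) -> List[TruthRecord]:
    """Copy genes to new loci as origin-labelled insertion-state events."""
    config = config or pack.config
    counts = dict(config.duplications_per_origin)
    if not counts:
        return []
    rng = _rng(config, 5)
    blocked = _blocked_tree(pack)
    for t in truth:
        blocked[t.chrom].addi(t.ref_start, t.ref_end)
    for g in pack.genes:
        blocked[g.chrom].addi(g.start, g.end)
    chroms = list(pack.genome)
    event_trees = {c: IntervalTree() for c in chroms}
    for t in truth:
        event_trees[t.chrom].addi(t.ref_start, t.ref_end)
    # source genes must not intersect any event (their sequence must be clean)
    clean_genes = [g for g in pack.genes
                   if not event_trees[g.chrom].overlap(g.start - 100, g.end + 100)]
    rng.shuffle(clean_genes)
    new_truth: List[TruthRecord] = []
    te_rows = []
    gi = 0
    mutator = next((f for f in sorted(pack.te_library)
                    if f.startswith("Mutator")), sorted(pack.te_library)[0])
    for origin in ("NAHR", "NHEJ", "TE"):
        for _ in range(counts.get(origin, 0)):
            if gi >= len(clean_genes):
                raise PlacementError(len(new_truth), sum(counts.values()))
            src = clean_genes[gi]
            gi += 1
            seg = mutate_subs(
                rng, pack.genome[src.chrom][src.start - 100:src.end + 100],
                config.duplication_divergence)
            chrom = chroms[int(rng.integers(len(chroms)))]
            seq = pack.genome[chrom]
            if origin == "TE":
                cons = pack.te_library[mutator]
                t_len = min(800, len(cons))
                te1 = mutate_subs(rng, cons[:t_len], 0.02)
                te2 = mutate_subs(rng, cons[-t_len:], 0.02)
                size = len(te1) + len(seg) + len(te2)
                s = _place(rng, blocked[chrom], len(seq), size, pad=1500)
                if s is None:
                    raise PlacementError(len(new_truth), sum(counts.values()))
                e = s + size
                seq[s:s + len(te1)] = te1
                seq[s + len(te1):s + len(te1) + len(seg)] = seg
                seq[e - len(te2):e] = te2
                te_rows.append((chrom, s, s + len(te1), mutator))
                te_rows.append((chrom, e - len(te2), e, mutator))
                gene_off = s + len(te1) + 100 - src.start
                rec = TruthRecord("", chrom, s, e, "NHR", "insertion", set(),
                                  origin="TE", source_gene_id=src.gene_id)
            elif origin == "NAHR":
                hom = random_seq(rng, 200, 0.5)
                size = 200 + len(seg)
                s = _place(rng, blocked[chrom], len(seq), size + 200, pad=1500)
                if s is None:
                    raise PlacementError(len(new_truth), sum(counts.values()))
                e = s + size
                seq[s:s + 200] = hom
                seq[s + 200:e] = seg
                seq[e:e + 200] = mutate_subs(rng, hom, 0.02)
                gene_off = s + 200 + 100 - src.start
                rec = TruthRecord("", chrom, s, e, "NAHR", "insertion", set(),
                                  homology_len=200, origin="NAHR",
                                  source_gene_id=src.gene_id)
            else:  # NHEJ
                size = len(seg)
                s = _place(rng, blocked[chrom], len(seq), size + 12, pad=1500)
                if s is None:
                    raise PlacementError(len(new_truth), sum(counts.values()))
                e = s + size
                seq[s:e] = seg
                mh = int(rng.integers(3, 9))
                seq[e:e + mh] = seq[s:s + mh]
                _force_mismatch(pack.genome, chrom, e + mh, s + mh)
                _force_mismatch(pack.genome, chrom, e - 1, s - 1)
                gene_off = s + 100 - src.start
                rec = TruthRecord("", chrom, s, e, "NHR", "insertion", set(),
                                  microhomology_len=mh, origin="NHEJ",
                                  source_gene_id=src.gene_id)
            if origin != "NHEJ":  # keep the enforced microhomology intact
                _force_mismatch(pack.genome, chrom, e, s)
            new_gene = GeneModel(
                gene_id=f"{src.gene_id}_dup", chrom=chrom,
                start=src.start + gene_off, end=src.end + gene_off,
                strand=src.strand,
                exons=[(a + gene_off, b + gene_off) for a, b in src.exons],
                cds=[(a + gene_off, b + gene_off) for a, b in src.cds],
                utr5=[(a + gene_off, b + gene_off) for a, b in src.utr5],
                utr3=[(a + gene_off, b + gene_off) for a, b in src.utr3])
            new_gene.validate()
            pack.genes.append(new_gene)
            rec.gene_id = new_gene.gene_id
            rec.carrier_accessions = _draw_carriers(rng, config)
            new_truth.append(rec)
    if te_rows:
        pack.te = pd.concat(
            [pack.te, pd.DataFrame(te_rows, columns=pack.te.columns)],
            ignore_index=True).sort_values(["chrom", "start"]).reset_index(drop=True)
    pack.genes.sort(key=lambda g: (g.chrom, g.start))
    truth.extend(new_truth)
    truth.sort(key=lambda t: (t.chrom, t.ref_start))
    for i, t in enumerate(truth):
        t.event_id = f"ev_{i + 1:04d}"
    return new_truth
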