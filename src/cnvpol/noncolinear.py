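"""Origin of CNV genes at non-co-linear positions.

A CNV gene is co-linear when its projected outgroup window contains its
exonic sequence; genes inside reference-lineage insertions are not. For a
non-co-linear gene, a recent duplication leaves an ancestral copy
elsewhere in the reference: ``find_ancestral_copy`` runs a seed-and-extend
homolog search (exact 16-mer seeding, edlib verification) over the whole
genome, excluding self-hits. For high-identity pairs the duplication
mechanism is read from the breakpoint context of the new copy:
TE copies flanking both sides (transposon-mediated capture), extended
flanking homology (NAHR), or junction microhomology (NHEJ).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .config import MechanismParams, OriginParams
from .impact import GeneModel
from .io import Genome, array_to_seq
from .mechanism import flanking_homology, junction_microhomology
from .polarize import (PolarizeParams, SyntenyBlock, _probe_hits, _tile,
                       project_to_outgroup)


@dataclass
class AncestralHit:
    chrom: str
    start: int
    end: int
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NoncolinearCall:
    gene_id: str
    is_colinear: bool
    ancestral_chrom: str = ""
    ancestral_start: int = -1
    ancestral_end: int = -1
    ancestral_identity: float = float("nan")
    origin_mechanism: str = ""  # TE | NHEJ | NAHR | unresolved | ""


def is_colinear(gene: GeneModel, blocks: Sequence[SyntenyBlock],
                ref: Genome, out: Genome,
                params: OriginParams | None = None,
                pol_params: PolarizeParams | None = None) -> bool:
    """Exonic sequence must align into the projected outgroup window."""
    params = params or OriginParams()
    pol_params = pol_params or PolarizeParams()
    proj = project_to_outgroup(gene.chrom, gene.start, gene.end, blocks)
    if proj is None:
        return False
    out_seq = out[proj.out_chrom]
    w_s = max(0, proj.start - pol_params.flank - proj.margin)
    w_e = min(len(out_seq), proj.end + pol_params.flank + proj.margin)
    if w_e <= w_s:
        return False
    window = array_to_seq(out_seq[w_s:w_e])
    probes: List[str] = []
    for s, e in gene.exons:
        exon = array_to_seq(ref[gene.chrom][s:e])
        probes.extend(_tile(exon, pol_params))
    if not probes:
        return False
    frac = _probe_hits(probes, window, pol_params.probe_min_identity) / len(probes)
    return frac >= params.min_coverage


# ------------------------------------------------- seed-and-extend search

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _kmer_codes(seq: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer codes per position; positions touching non-ACGT -> max."""
    v = _CODE[seq]
    n = len(seq) - k + 1
    if n <= 0:
        return np.array([], dtype=np.uint64)
    code = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        w = v[i:i + n]
        code = code * 4 + np.minimum(w, 3).astype(np.uint64)
        bad |= w == 4
    code[bad] = np.uint64(2 ** 63)
    return code


class GenomeIndex:
    """Per-chromosome packed k-mer arrays for exact-seed lookup."""

    def __init__(self, genome: Genome, k: int = 16):
        self.k = k
        self.genome = genome
        self.codes: Dict[str, np.ndarray] = {
            c: _kmer_codes(s, k) for c, s in genome.items()}

    def seed_hits(self, query: np.ndarray, stride: int = 32,
                  ) -> Dict[str, List[Tuple[int, int]]]:
        """(genome_pos, query_pos) exact matches of strided query seeds."""
        k = self.k
        q_codes = _kmer_codes(query, k)
        if len(q_codes) == 0:
            return {}
        q_pos = np.arange(0, len(q_codes), stride)
        seeds = q_codes[q_pos]
        ok = seeds != np.uint64(2 ** 63)
        seeds, q_pos = seeds[ok], q_pos[ok]
        lookup = {}
        for code, qp in zip(seeds.tolist(), q_pos.tolist()):
            lookup.setdefault(code, []).append(qp)
        hits: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, codes in self.codes.items():
            mask = np.isin(codes, seeds)
            pos = np.flatnonzero(mask)
            pairs = []
            for p in pos.tolist():
                for qp in lookup.get(int(codes[p]), []):
                    pairs.append((p, qp))
            if pairs:
                hits[chrom] = pairs
        return hits


def find_ancestral_copy(gene: GeneModel, ref: Genome,
                        index: GenomeIndex | None = None,
                        params: OriginParams | None = None,
                        ) -> Optional[AncestralHit]:
    """Best non-self genomic homolog of the gene span, or None.

    Exact k-mer seeds are clustered by diagonal; candidate windows are
    verified by infix alignment of the whole gene span. A hit qualifies at
    identity >= min_identity; ties break by identity, then length, then
    leftmost position. Hits overlapping the query span are discarded.
    """
    params = params or OriginParams()
    if gene.end - gene.start < 200:
        return None
    index = index or GenomeIndex(ref, params.seed_k)
    query = ref[gene.chrom][gene.start:gene.end]
    qlen = len(query)
    candidates: List[Tuple[str, int, int]] = []
    for chrom, pairs in index.seed_hits(query).items():
        diags: Dict[int, int] = {}
        for p, qp in pairs:
            d = (p - qp) // 100  # coarse diagonal band
            diags[d] = diags.get(d, 0) + 1
        for d, count in diags.items():
            if count < 3:
                continue
            start = max(0, d * 100 - 300)
            end = min(len(ref[chrom]), d * 100 + qlen + 400)
            candidates.append((chrom, start, end))
    best: Optional[AncestralHit] = None
    for chrom, start, end in sorted(candidates):
        target = array_to_seq(ref[chrom][start:end])
        r = edlib.align(array_to_seq(query), target, mode="HW", task="locations")
        if r["editDistance"] < 0 or not r["locations"]:
            continue
        identity = 1.0 - r["editDistance"] / qlen
        if identity < params.min_identity:
            continue
        # candidate windows may cover the query itself (tandem copies):
        # walk the tie locations and keep the first non-self hit
        for loc in r["locations"][:8]:
            hit = AncestralHit(chrom=chrom, start=start + loc[0],
                               end=start + loc[1] + 1, identity=identity)
            if hit.length < 0.5 * qlen:
                continue
            if (chrom == gene.chrom
                    and min(hit.end, gene.end) > max(hit.start, gene.start)):
                continue
            key = (round(identity, 6), hit.length, -hit.start)
            if best is None or key > (round(best.identity, 6), best.length,
                                      -best.start):
                best = hit
            break
    if best is not None:
        assert not (best.chrom == gene.chrom
                    and min(best.end, gene.end) > max(best.start, gene.start))
    return best


# ---------------------------------------------------------------- origin

def _dup_boundaries(gene: GeneModel, hit: AncestralHit, ref: Genome,
                    window: int = 3000, block: int = 50,
                    min_block_identity: float = 0.8) -> Tuple[int, int]:
    """Extend the new-copy/ancestral-copy alignment outward in 50-bp blocks
    until identity drops; substitution-only comparison."""
    seq = ref[gene.chrom]
    src = ref[hit.chrom]
    # assume co-linear copies: source position of gene.start
    src_start = hit.start
    left = 0
    for off in range(block, window + 1, block):
        a = seq[gene.start - off:gene.start - off + block]
        b = src[src_start - off:src_start - off + block]
        if len(a) < block or len(b) < block or np.mean(a == b) < min_block_identity:
            break
        left = off
    src_end = hit.end
    right = 0
    for off in range(0, window, block):
        a = seq[gene.end + off:gene.end + off + block]
        b = src[src_end + off:src_end + off + block]
        if len(a) < block or len(b) < block or np.mean(a == b) < min_block_identity:
            break
        right = off + block
    return gene.start - left, gene.end + right


def infer_origin(gene: GeneModel, hit: AncestralHit, ref: Genome,
                 te: pd.DataFrame,
                 mech_params: MechanismParams | None = None,
                 params: OriginParams | None = None,
                 event: Tuple[int, int] | None = None) -> str:
    """TE / NAHR / NHEJ / unresolved for one high-identity duplicate pair.

    ``event`` supplies the duplication boundaries (the containing CNV's
    refined breakpoints); without it, boundaries are estimated by aligned
    extension around the copy. Precedence: TE flanking both sides of the
    new copy -> extended junction homology (NAHR) -> junction
    microhomology (NHEJ) -> unresolved.
    """
    mech_params = mech_params or MechanismParams()
    params = params or OriginParams()
    if hit.identity < params.origin_min_identity:
        return ""
    w = params.te_flank_window
    sub = te[te["chrom"] == gene.chrom]
    left_te = ((sub["end"] > gene.start - w) & (sub["start"] < gene.start)).any()
    right_te = ((sub["end"] > gene.end) & (sub["start"] < gene.end + w)).any()
    if left_te and right_te:
        return "TE"
    if event is not None:
        bs, be = event
    else:
        bs, be = _dup_boundaries(gene, hit, ref)
    seq = ref[gene.chrom]
    bs, be = max(0, bs), min(len(seq), be)
    if be - bs < 50:
        return "unresolved"
    hom_len, hom_id = flanking_homology(seq, bs, be, mech_params)
    if hom_len >= mech_params.nahr_min_len and hom_id >= mech_params.nahr_min_identity:
        return "NAHR"
    _, _, mh = junction_microhomology(seq, bs, be,
                                      cap=mech_params.homology_scan_window)
    if mh <= mech_params.mh_max:
        return "NHEJ"
    return "unresolved"


def analyze_cnv_genes(genes: Sequence[GeneModel], cnv_events,
                      blocks: Sequence[SyntenyBlock], ref: Genome,
                      out: Genome, te: pd.DataFrame,
                      mech_params: MechanismParams | None = None,
                      params: OriginParams | None = None,
                      pol_params: PolarizeParams | None = None,
                      ) -> List[NoncolinearCall]:
    """Full non-co-linearity + origin analysis for a set of CNV genes.

    ``cnv_events`` provide insertion-state intervals whose breakpoints
    serve as duplication boundaries for fully contained genes.
    """
    params = params or OriginParams()
    index = GenomeIndex(ref, params.seed_k)
    ins_events = [e for e in cnv_events
                  if getattr(e, "ancestral_state", None) == "insertion"]
    calls: List[NoncolinearCall] = []
    for gene in genes:
        colinear = is_colinear(gene, blocks, ref, out, params, pol_params)
        call = NoncolinearCall(gene_id=gene.gene_id, is_colinear=colinear)
        if not colinear:
            hit = find_ancestral_copy(gene, ref, index, params)
            if hit is not None:
                call.ancestral_chrom = hit.chrom
                call.ancestral_start, call.ancestral_end = hit.start, hit.end
                call.ancestral_identity = hit.identity
                event = next(
                    ((e.start, e.end) for e in ins_events
                     if e.chrom == gene.chrom and e.start <= gene.start
                     and gene.end <= e.end), None)
                call.origin_mechanism = infer_origin(
                    gene, hit, ref, te, mech_params, params, event=event)
        calls.append(call)
    return calls


def calls_to_frame(calls: Sequence[NoncolinearCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": c.gene_id, "is_colinear": c.is_colinear,
        "ancestral_chrom": c.ancestral_chrom,
        "ancestral_start": c.ancestral_start,
        "ancestral_end": c.ancestral_end,
        "ancestral_identity": (round(c.ancestral_identity, 4)
                               if c.ancestral_identity == c.ancestral_identity
                               else ""),
        "origin_mechanism": c.origin_mechanism,
    } for c in calls], columns=["gene_id", "is_colinear", "ancestral_chrom",
                                "ancestral_start", "ancestral_end",
                                "ancestral_identity", "origin_mechanism"])
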