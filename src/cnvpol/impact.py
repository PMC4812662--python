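"""Gene impact of CNVs, population sharing, and term enrichment.

A CNV overlapping a gene is categorised by precedence: ``full`` if the
event contains the whole annotated gene span; else ``partial_cds`` if it
touches coding sequence; else ``utr_only``; else ``intron_only``. Genes are
counted once per category per event pair; summaries count distinct genes,
the way catalog overview tables count them.

Population sharing labels every event by the group membership of its
carrier accessions (cultivated/wild, and the indica/japonica subspecies
partition). Enrichment is the classical upper-tail hypergeometric test per
term with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


class InputError(ValueError):
    pass


Interval = Tuple[int, int]


@dataclass
class GeneModel:
    """A gene with exon/CDS/UTR structure (0-based half-open intervals)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def validate(self) -> None:
        def _check_list(name: str, ivs: List[Interval]) -> None:
            prev_end = -1
            for s, e in sorted(ivs):
                if s >= e or s < self.start or e > self.end:
                    raise InputError(
                        f"gene {self.gene_id}: bad {name} interval [{s},{e})")
                if s < prev_end:
                    raise InputError(
                        f"gene {self.gene_id}: overlapping {name} intervals")
                prev_end = e

        if self.start >= self.end:
            raise InputError(f"gene {self.gene_id}: empty span")
        for name in ("exons", "cds", "utr5", "utr3"):
            _check_list(name, getattr(self, name))
        for name in ("cds", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise InputError(
                        f"gene {self.gene_id}: {name} interval [{s},{e}) "
                        f"outside exons")

    @property
    def utr(self) -> List[Interval]:
        return self.utr5 + self.utr3


@dataclass
class GeneImpact:
    gene_id: str
    event_id: str
    category: str  # full | partial_cds | utr_only | intron_only


def _intersects(a: Interval, ivs: Iterable[Interval]) -> bool:
    s, e = a
    return any(min(e, ie) > max(s, is_) for is_, ie in ivs)


def classify_gene_impact(events, genes: Sequence[GeneModel],
                         ) -> Tuple[List[GeneImpact], Dict[str, int]]:
    """Categorise every overlapping (gene, event) pair; summarise genes.

    Summary counts are over distinct genes per category (a gene takes its
    highest-precedence category across events) plus distinct gene-hitting
    CNVs, and ``cds_disrupted_genes`` = genes hit full or partial_cds.
    """
    for g in genes:
        g.validate()
    trees: Dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, i)

    records: List[GeneImpact] = []
    for ev in events:
        tree = trees.get(ev.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(ev.start, ev.end),
                          key=lambda h: h.begin):
            g = genes[hit.data]
            iv = (ev.start, ev.end)
            if ev.start <= g.start and g.end <= ev.end:
                cat = "full"
            elif _intersects(iv, g.cds):
                cat = "partial_cds"
            elif _intersects(iv, g.utr):
                cat = "utr_only"
            else:
                cat = "intron_only"
            records.append(GeneImpact(g.gene_id, ev.event_id, cat))

    precedence = {"full": 0, "partial_cds": 1, "utr_only": 2, "intron_only": 3}
    best: Dict[str, str] = {}
    for r in records:
        if (r.gene_id not in best
                or precedence[r.category] < precedence[best[r.gene_id]]):
            best[r.gene_id] = r.category
    summary = {
        "genes_affected": len(best),
        "cnvs_hitting_genes": len({r.event_id for r in records}),
        "full": sum(1 for c in best.values() if c == "full"),
        "partial_cds": sum(1 for c in best.values() if c == "partial_cds"),
        "utr_only": sum(1 for c in best.values() if c == "utr_only"),
        "intron_only": sum(1 for c in best.values() if c == "intron_only"),
    }
    summary["cds_disrupted_genes"] = summary["full"] + summary["partial_cds"]
    return records, summary


def impacts_to_frame(records: Sequence[GeneImpact]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "event_id": r.event_id,
          "category": r.category} for r in records],
        columns=["gene_id", "event_id", "category"])


# ------------------------------------------------------------ sharing

def population_sharing(events, groups: pd.DataFrame) -> pd.DataFrame:
    """Label each event by carrier group composition.

    ``groups`` columns: accession, group (cultivated|wild), subgroup
    (indica|japonica|other). Returns one row per event with a
    cultivated/wild label (shared | cultivated_only | wild_only) and an
    indica/japonica label (shared | indica_only | japonica_only | neither,
    computed over carriers belonging to those subgroups only).
    """
    grp = dict(zip(groups["accession"], groups["group"]))
    sub = dict(zip(groups["accession"], groups["subgroup"]))
    rows = []
    for ev in events:
        carriers = sorted(ev.carrier_accessions)
        missing = [a for a in carriers if a not in grp]
        if missing:
            raise InputError(f"unlabeled accessions: {missing}")
        gset = {grp[a] for a in carriers}
        if gset == {"cultivated"}:
            label = "cultivated_only"
        elif gset == {"wild"}:
            label = "wild_only"
        else:
            label = "shared"
        sset = {sub[a] for a in carriers if sub[a] in ("indica", "japonica")}
        if not sset:
            sublabel = "neither"
        elif sset == {"indica"}:
            sublabel = "indica_only"
        elif sset == {"japonica"}:
            sublabel = "japonica_only"
        else:
            sublabel = "shared"
        rows.append({"event_id": ev.event_id, "cultivated_wild": label,
                     "indica_japonica": sublabel})
    return pd.DataFrame(rows, columns=["event_id", "cultivated_wild",
                                       "indica_japonica"])


def sharing_fractions(sharing: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    """Fractions per partition; each partition's fractions sum to 1."""
    out = {}
    for col in ("cultivated_wild", "indica_japonica"):
        counts = sharing[col].value_counts()
        n = int(counts.sum())
        out[col] = {k: int(v) / n for k, v in counts.items()} if n else {}
    return out


# --------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # study hits
    n: int  # study size
    K: int  # population hits
    N: int  # population size
    p_value: float
    fdr: float = 1.0


def hypergeom_enrichment(study_genes: Set[str],
                         term_map: Mapping[str, Set[str]],
                         universe: Set[str],
                         alpha: float = 0.05) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per term, BH-adjusted.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|term genes|,
    n=|study|). Terms with no gene in the universe are skipped.
    """
    extra = study_genes - universe
    if extra:
        raise InputError(f"study genes outside universe: {sorted(extra)[:10]}")
    bad = set(term_map) - universe
    if bad:
        raise InputError(f"term_map keys outside universe: {sorted(bad)[:10]}")
    terms: Dict[str, Set[str]] = {}
    for gene, ts in term_map.items():
        for t in ts:
            terms.setdefault(t, set()).add(gene)
    N, n = len(universe), len(study_genes)
    results = []
    for term in sorted(terms):
        K = len(terms[term] & universe)
        if K == 0:
            continue
        k = len(terms[term] & study_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, min(p, 1.0)))
    if results:
        fdr = stats.false_discovery_control(
            [r.p_value for r in results], method="bh")
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "p_value": r.p_value, "fdr": r.fdr} for r in results],
        columns=["term_id", "k", "n", "K", "N", "p_value", "fdr"])
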