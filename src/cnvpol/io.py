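"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open everywhere in memory; GFF3 (1-based,
closed) and VCF (1-based POS, INFO END inclusive) are converted at these
boundaries only. Sequences travel as numpy uint8 arrays of ASCII codes so
the simulator can mutate them vectorised.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd
from pyfaidx import Fasta

Genome = Dict[str, np.ndarray]  # chrom -> uint8 ASCII array


# ---------------------------------------------------------------- sequences

def seq_to_array(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(a: np.ndarray) -> str:
    return a.tobytes().decode("ascii")


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            s = array_to_seq(genome[chrom])
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> Genome:
    fa = Fasta(str(path), rebuild=True, build_index=True)
    genome = {name: seq_to_array(str(fa[name][:])) for name in fa.keys()}
    fa.close()
    return genome


# -------------------------------------------------------------- BED and TSV

def write_bed(df: pd.DataFrame, path, columns: Iterable[str]) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=list(columns))


def read_bed(path, columns: List[str]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", header=None, names=columns)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=columns)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------------- GFF3

GFF_COLS = ["seqid", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes"]


def write_genes_gff3(genes, path) -> None:
    """Write GeneModel records (see cnvpol.impact) as a minimal GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            def line(ftype, s, e, attrs):
                fh.write("\t".join([
                    g.chrom, "cnvpol", ftype, str(s + 1), str(e),
                    ".", g.strand, ".", attrs]) + "\n")
            line("gene", g.start, g.end, f"ID={g.gene_id}")
            mrna = f"{g.gene_id}.1"
            line("mRNA", g.start, g.end, f"ID={mrna};Parent={g.gene_id}")
            for s, e in g.exons:
                line("exon", s, e, f"Parent={mrna}")
            for s, e in g.cds:
                line("CDS", s, e, f"Parent={mrna}")
            for s, e in g.utr5:
                line("five_prime_UTR", s, e, f"Parent={mrna}")
            for s, e in g.utr3:
                line("three_prime_UTR", s, e, f"Parent={mrna}")


def read_genes_gff3(path):
    """Parse the GFF3 subset written above back into GeneModel records."""
    from .impact import GeneModel

    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=GFF_COLS, dtype={"seqid": str})
    genes: Dict[str, GeneModel] = {}
    mrna_to_gene: Dict[str, str] = {}

    def attr(attrs: str, key: str) -> str:
        for part in attrs.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1:]
        return ""

    for row in df.itertuples(index=False):
        start, end = int(row.start) - 1, int(row.end)
        if row.type == "gene":
            gid = attr(row.attributes, "ID")
            genes[gid] = GeneModel(gene_id=gid, chrom=str(row.seqid),
                                   start=start, end=end, strand=row.strand,
                                   exons=[], cds=[], utr5=[], utr3=[])
        elif row.type == "mRNA":
            mrna_to_gene[attr(row.attributes, "ID")] = attr(row.attributes, "Parent")
        else:
            parent = attr(row.attributes, "Parent")
            gid = mrna_to_gene.get(parent, parent)
            g = genes[gid]
            target = {"exon": g.exons, "CDS": g.cds,
                      "five_prime_UTR": g.utr5,
                      "three_prime_UTR": g.utr3}.get(row.type)
            if target is not None:
                target.append((start, end))
    out = list(genes.values())
    for g in out:
        for lst in (g.exons, g.cds, g.utr5, g.utr3):
            lst.sort()
        g.validate()
    return out


# --------------------------------------------------------------------- VCF

VCF_HEADER = """##fileformat=VCFv4.2
##source=cnvpol
##ALT=<ID=DEL,Description="Deletion relative to the reference">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Breakpoints not at single-nucleotide resolution">
##INFO=<ID=SUPP_CALLERS,Number=1,Type=String,Description="Callers supporting the consensus, per carrier accession (acc:PE+SR|...)">
##INFO=<ID=N_ACC,Number=1,Type=Integer,Description="Number of carrier accessions">
##INFO=<ID=CARRIERS,Number=1,Type=String,Description="Pipe-separated carrier accessions">
##INFO=<ID=ANC_STATE,Number=1,Type=String,Description="Ancestral state: insertion/deletion/undefined">
##INFO=<ID=MECH,Number=1,Type=String,Description="Formation mechanism">
"""


def write_consensus_vcf(events, path, contigs: Dict[str, int]) -> None:
    """Write ConsensusCnv records (cnvpol.merge) as a deletion-only VCF."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for ev in events:
            # symbolic-DEL convention: POS is the (1-based) padding base
            # before the deleted segment, END the last deleted base; for a
            # 0-based half-open interval both equal start and end.
            info = [
                "SVTYPE=DEL",
                f"END={ev.end}",
                f"SVLEN=-{ev.end - ev.start}",
            ]
            if not ev.precise:
                info.append("IMPRECISE")
            supp = "|".join(
                f"{acc}:" + "+".join(sorted(cs))
                for acc, cs in sorted(ev.supporting_callers.items()))
            info.append(f"SUPP_CALLERS={supp}")
            info.append(f"N_ACC={ev.n_accessions}")
            info.append(f"CARRIERS={'|'.join(sorted(ev.carrier_accessions))}")
            if getattr(ev, "ancestral_state", None):
                info.append(f"ANC_STATE={ev.ancestral_state}")
            if getattr(ev, "mechanism", None):
                info.append(f"MECH={ev.mechanism}")
            fh.write("\t".join([
                ev.chrom, str(max(1, ev.start)), ev.event_id, "N", "<DEL>",
                ".", "PASS", ";".join(info)]) + "\n")


def read_consensus_vcf(path):
    """Read a deletion VCF (ours or SVTYPE=DEL/END from elsewhere)."""
    import pysam

    from .merge import ConsensusCnv

    events = []
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            info = rec.info
            if info.get("SVTYPE", "DEL") != "DEL":
                continue
            start = rec.pos  # POS is the padding base; deletion starts after it
            end = int(info["END"]) if "END" in info else rec.stop
            def info_str(key: str) -> str:
                v = info.get(key, "")
                return ",".join(v) if isinstance(v, tuple) else str(v)

            supp = {}
            if "SUPP_CALLERS" in info:
                for part in info_str("SUPP_CALLERS").split("|"):
                    acc, callers = part.split(":")
                    supp[acc] = set(callers.split("+"))
            carriers = (set(info_str("CARRIERS").split("|"))
                        if "CARRIERS" in info else set(supp))
            ev = ConsensusCnv(
                event_id=rec.id or f"cnv_{i:05d}",
                chrom=rec.chrom, start=start, end=end,
                precise="IMPRECISE" not in info,
                supporting_callers=supp,
                carrier_accessions=carriers,
                n_accessions=int(info.get("N_ACC", len(carriers))),
            )
            ev.ancestral_state = info.get("ANC_STATE")
            ev.mechanism = info.get("MECH")
            events.append(ev)
    return events


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
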