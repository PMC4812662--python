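"""Assemble a full simulated dataset and write it to disk.

Output layout mirrors the pipeline's external interfaces: reference.fa,
outgroup.fa, genes.gff3, te.bed, vntr.bed, gaps.bed, anchors.tsv,
truth.tsv, terms.tsv, groups.tsv and calls/<accession>.<caller>.bed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List

import pandas as pd

from ..config import SimConfig
from .. import io
from .callers import emit_callsets
from .events import TruthRecord, implant_duplications, implant_events, truth_to_frame
from .outgroup import OutgroupPack, mutate_outgroup
from .reference import GenomePack, simulate_reference


@dataclass
class Simulation:
    pack: GenomePack
    truth: List[TruthRecord]
    out: OutgroupPack
    calls: pd.DataFrame
    groups: pd.DataFrame


def make_groups(config: SimConfig) -> pd.DataFrame:
    """Accession group labels at the study's 4:1 cultivated:wild ratio.

    Cultivated accessions split roughly japonica:indica:other = 5:4:1,
    wild accessions carry subgroup 'other'.
    """
    n = config.n_accessions
    n_wild = max(1, round(n / 5)) if n >= 2 else 0
    n_cult = n - n_wild
    n_jap = round(n_cult * 0.5)
    n_ind = round(n_cult * 0.4)
    rows = []
    for i in range(n):
        acc = f"acc{i + 1:02d}"
        if i < n_jap:
            rows.append((acc, "cultivated", "japonica"))
        elif i < n_jap + n_ind:
            rows.append((acc, "cultivated", "indica"))
        elif i < n_cult:
            rows.append((acc, "cultivated", "other"))
        else:
            rows.append((acc, "wild", "other"))
    return pd.DataFrame(rows, columns=["accession", "group", "subgroup"])


def simulate_all(config: SimConfig) -> Simulation:
    """Run the whole generator: reference, events, outgroup, call sets."""
    pack = simulate_reference(config)
    truth = implant_events(pack, config)
    if config.duplications_per_origin:
        implant_duplications(pack, truth, config)
    out = mutate_outgroup(pack, truth, config)
    calls = emit_callsets(truth, config)
    return Simulation(pack=pack, truth=truth, out=out, calls=calls,
                      groups=make_groups(config))


def write_outputs(sim: Simulation, outdir: str) -> None:
    io.ensure_dir(outdir)
    p = lambda name: os.path.join(outdir, name)
    io.write_fasta(sim.pack.genome, p("reference.fa"))
    io.write_fasta(sim.out.outgroup, p("outgroup.fa"))
    io.write_genes_gff3(sim.pack.genes, p("genes.gff3"))
    io.write_bed(sim.pack.te, p("te.bed"), ["chrom", "start", "end", "family"])
    io.write_bed(sim.pack.vntr, p("vntr.bed"),
                 ["chrom", "start", "end", "period"])
    io.write_bed(sim.out.gaps, p("gaps.bed"), ["chrom", "start", "end"])
    io.write_tsv(sim.out.anchors, p("anchors.tsv"))
    io.write_tsv(truth_to_frame(sim.truth), p("truth.tsv"))
    io.write_tsv(sim.pack.terms, p("terms.tsv"))
    io.write_tsv(sim.groups, p("groups.tsv"))
    calls_dir = io.ensure_dir(p("calls"))
    for (acc, caller), sub in sim.calls.groupby(["accession", "caller"]):
        path = os.path.join(calls_dir, f"{acc}.{caller}.bed")
        out = sub.copy()
        io.write_bed(out, path, ["chrom", "start", "end", "caller", "accession"])


def read_calls_dir(calls_dir: str) -> pd.DataFrame:
    """Read back calls/<accession>.<caller>.bed files into one frame."""
    frames = []
    for name in sorted(os.listdir(calls_dir)):
        if not name.endswith(".bed"):
            continue
        df = io.read_bed(os.path.join(calls_dir, name),
                         ["chrom", "start", "end", "caller", "accession"])
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "caller", "accession"])
    return pd.concat(frames, ignore_index=True)
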