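"""End-to-end orchestration: simulate -> merge -> polarize -> classify ->
annotate -> origin -> report.

Every stage reads its inputs from files written by earlier stages and
writes its outputs before the next stage starts, so stages can also run
standalone from the CLI. The report is re-derived from the stage files at
report time — no counts are cached across stages.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import io
from .config import (MechanismParams, MergeParams, OriginParams,
                     PolarizeParams, SimConfig, sim_config_from_dict)
from .impact import (classify_gene_impact, enrichment_to_frame,
                     hypergeom_enrichment, impacts_to_frame,
                     population_sharing, sharing_fractions)
from .mechanism import (calls_to_frame as mech_to_frame, classify_all,
                        summarize_mechanisms)
from .merge import calls_from_frame, events_to_frame, merge_callsets
from .noncolinear import analyze_cnv_genes, calls_to_frame as nc_to_frame
from .polarize import (PolarizedCnv, anchors_from_frame, build_blocks,
                       polarize_events, polarized_to_frame)
from .sim import simulate_all, write_outputs
from .sim.write import read_calls_dir

log = logging.getLogger("cnvpol")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class IntegrityError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    sim: SimConfig = field(default_factory=SimConfig)
    merge: MergeParams = field(default_factory=MergeParams)
    polarize: PolarizeParams = field(default_factory=PolarizeParams)
    mechanism: MechanismParams = field(default_factory=MechanismParams)
    origin: OriginParams = field(default_factory=OriginParams)
    log_level: str = "INFO"


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def run_config_from_dict(data: dict) -> RunConfig:
    return RunConfig(
        outdir=data.get("outdir", "cnvpol_run"),
        sim=sim_config_from_dict(data.get("sim", {})),
        merge=MergeParams(**data.get("merge", {})),
        polarize=PolarizeParams(**data.get("polarize", {})),
        mechanism=MechanismParams(**data.get("mechanism", {})),
        origin=OriginParams(**data.get("origin", {})),
        log_level=data.get("log_level", "INFO"),
    )


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def _contigs(datadir: str) -> Dict[str, int]:
    genome = io.read_fasta(_require(os.path.join(datadir, "reference.fa")))
    return {c: len(s) for c, s in genome.items()}


# ------------------------------------------------------------------ stages

def stage_simulate(config: SimConfig, outdir: str):
    sim = simulate_all(config)
    write_outputs(sim, outdir)
    log.info("simulate: %d truth events, %d calls, %d accessions",
             len(sim.truth), len(sim.calls), config.n_accessions)
    return sim


def stage_merge(datadir: str, outdir: str,
                params: Optional[MergeParams] = None) -> pd.DataFrame:
    params = params or MergeParams()
    calls_df = read_calls_dir(_require(os.path.join(datadir, "calls")))
    events = merge_callsets(calls_from_frame(calls_df), params)
    df = events_to_frame(events)
    io.ensure_dir(outdir)
    io.write_tsv(df, os.path.join(outdir, "consensus.tsv"))
    io.write_consensus_vcf(events, os.path.join(outdir, "consensus.vcf"),
                           _contigs(datadir))
    log.info("merge: %d calls -> %d consensus events", len(calls_df), len(events))
    return df


def _events_from_consensus(outdir: str) -> List[PolarizedCnv]:
    df = io.read_tsv(_require(os.path.join(outdir, "consensus.tsv")))
    events = []
    for r in df.itertuples(index=False):
        events.append(PolarizedCnv(
            event_id=str(r.event_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), precise=bool(r.precise), ancestral_state="",
            carrier_accessions=set(str(r.carriers).split(","))))
    return events


def stage_polarize(datadir: str, outdir: str,
                   params: Optional[PolarizeParams] = None) -> pd.DataFrame:
    params = params or PolarizeParams()
    events = _events_from_consensus(outdir)
    ref = io.read_fasta(_require(os.path.join(datadir, "reference.fa")))
    out = io.read_fasta(_require(os.path.join(datadir, "outgroup.fa")))
    anchors = anchors_from_frame(
        io.read_tsv(_require(os.path.join(datadir, "anchors.tsv"))))
    gaps = io.read_bed(os.path.join(datadir, "gaps.bed"),
                       ["chrom", "start", "end"])
    pols = polarize_events(events, ref, out, gaps, anchors, params)
    df = polarized_to_frame(pols)
    io.write_tsv(df, os.path.join(outdir, "polarized.tsv"))
    counts = df["ancestral_state"].value_counts().to_dict()
    log.info("polarize: %s", counts)
    return df


def _events_from_polarized(outdir: str) -> List[PolarizedCnv]:
    df = io.read_tsv(_require(os.path.join(outdir, "polarized.tsv")))
    events = []
    for r in df.itertuples(index=False):
        events.append(PolarizedCnv(
            event_id=str(r.event_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), precise=bool(r.precise),
            ancestral_state=str(r.ancestral_state),
            carrier_accessions=set(str(r.carriers).split(","))))
    return events


def stage_mechanism(datadir: str, outdir: str,
                    params: Optional[MechanismParams] = None) -> pd.DataFrame:
    params = params or MechanismParams()
    events = _events_from_polarized(outdir)
    ref = io.read_fasta(_require(os.path.join(datadir, "reference.fa")))
    te = io.read_bed(_require(os.path.join(datadir, "te.bed")),
                     ["chrom", "start", "end", "family"])
    vntr = io.read_bed(_require(os.path.join(datadir, "vntr.bed")),
                       ["chrom", "start", "end", "period"])
    calls = classify_all(events, ref, te, vntr, params)
    df = mech_to_frame(calls)
    io.write_tsv(df, os.path.join(outdir, "mechanisms.tsv"))
    summary = summarize_mechanisms(calls, events)
    io.write_tsv(summary["distribution"],
                 os.path.join(outdir, "mechanism_distribution.tsv"))
    io.write_tsv(summary["per_chromosome"],
                 os.path.join(outdir, "mechanism_per_chromosome.tsv"))
    log.info("mechanism: %s",
             df["mechanism"].value_counts().to_dict())
    return df


def stage_impact(datadir: str, outdir: str,
                 alpha: float = 0.05) -> Dict[str, pd.DataFrame]:
    events = _events_from_polarized(outdir)
    genes = io.read_genes_gff3(_require(os.path.join(datadir, "genes.gff3")))
    records, summary = classify_gene_impact(events, genes)
    impact_df = impacts_to_frame(records)
    io.write_tsv(impact_df, os.path.join(outdir, "gene_impact.tsv"))
    io.write_tsv(pd.DataFrame([summary]),
                 os.path.join(outdir, "gene_impact_summary.tsv"))

    groups = io.read_tsv(_require(os.path.join(datadir, "groups.tsv")))
    sharing = population_sharing(events, groups)
    io.write_tsv(sharing, os.path.join(outdir, "sharing.tsv"))

    terms_path = os.path.join(datadir, "terms.tsv")
    enr_df = pd.DataFrame()
    if os.path.exists(terms_path):
        terms = io.read_tsv(terms_path)
        term_map: Dict[str, set] = {}
        for r in terms.itertuples(index=False):
            term_map.setdefault(str(r.gene_id), set()).add(str(r.term_id))
        universe = {g.gene_id for g in genes}
        disrupted = {r.gene_id for r in records
                     if r.category in ("full", "partial_cds")}
        results = hypergeom_enrichment(disrupted & universe,
                                       term_map, universe, alpha)
        enr_df = enrichment_to_frame(results)
        io.write_tsv(enr_df, os.path.join(outdir, "enrichment.tsv"))
    log.info("impact: %d gene-event pairs, %d genes affected",
             len(records), summary["genes_affected"])
    return {"impact": impact_df, "sharing": sharing, "enrichment": enr_df}


def stage_origin(datadir: str, outdir: str,
                 params: Optional[OriginParams] = None,
                 pol_params: Optional[PolarizeParams] = None) -> pd.DataFrame:
    params = params or OriginParams()
    pol_params = pol_params or PolarizeParams()
    impact_df = io.read_tsv(_require(os.path.join(outdir, "gene_impact.tsv")))
    cnv_gene_ids = set(impact_df["gene_id"].astype(str))
    genes = [g for g in io.read_genes_gff3(
        _require(os.path.join(datadir, "genes.gff3")))
        if g.gene_id in cnv_gene_ids]
    ref = io.read_fasta(_require(os.path.join(datadir, "reference.fa")))
    out = io.read_fasta(_require(os.path.join(datadir, "outgroup.fa")))
    anchors = anchors_from_frame(
        io.read_tsv(_require(os.path.join(datadir, "anchors.tsv"))))
    te = io.read_bed(_require(os.path.join(datadir, "te.bed")),
                     ["chrom", "start", "end", "family"])
    events = _events_from_polarized(outdir)
    blocks = build_blocks(anchors, max_gap=pol_params.max_anchor_gap)
    calls = analyze_cnv_genes(genes, events, blocks, ref, out, te,
                              params=params, pol_params=pol_params)
    df = nc_to_frame(calls)
    io.write_tsv(df, os.path.join(outdir, "noncolinear.tsv"))
    log.info("origin: %d CNV genes, %d non-co-linear",
             len(df), int((~df["is_colinear"]).sum()) if len(df) else 0)
    return df


# ------------------------------------------------------------------ report

def write_report(outdir: str) -> dict:
    """Machine- and human-readable summary, re-derived from stage files."""
    consensus = io.read_tsv(_require(os.path.join(outdir, "consensus.tsv")))
    polarized = io.read_tsv(_require(os.path.join(outdir, "polarized.tsv")))
    orphans = set(polarized["event_id"]) ^ set(consensus["event_id"])
    if orphans:
        raise IntegrityError(f"event_ids differ across stage files: {sorted(orphans)[:10]}")

    report: dict = {"n_events": int(len(consensus))}
    if len(consensus):
        sizes = consensus["length"]
        report["size"] = {
            "mean": float(sizes.mean()), "median": float(sizes.median()),
            "min": int(sizes.min()), "max": int(sizes.max())}
        report["precise_fraction"] = float(consensus["precise"].mean())
    pol_counts = polarized["ancestral_state"].value_counts().to_dict()
    n = max(1, len(polarized))
    report["polarity"] = {
        k: {"count": int(v), "fraction": int(v) / n}
        for k, v in sorted(pol_counts.items())}

    mech_path = os.path.join(outdir, "mechanism_distribution.tsv")
    if os.path.exists(mech_path):
        dist = io.read_tsv(mech_path)
        report["mechanisms"] = {
            str(r.mechanism): {"count": int(r.count),
                               "percent": float(r.percent),
                               "cumulative_bp": int(r.cumulative_bp)}
            for r in dist.itertuples(index=False)}
    gi_path = os.path.join(outdir, "gene_impact_summary.tsv")
    if os.path.exists(gi_path):
        report["gene_impact"] = {
            k: int(v) for k, v in io.read_tsv(gi_path).iloc[0].items()}
    sh_path = os.path.join(outdir, "sharing.tsv")
    if os.path.exists(sh_path):
        report["sharing"] = sharing_fractions(io.read_tsv(sh_path))
    nc_path = os.path.join(outdir, "noncolinear.tsv")
    if os.path.exists(nc_path):
        nc = io.read_tsv(nc_path)
        report["noncolinear"] = {
            "n_cnv_genes": int(len(nc)),
            "n_noncolinear": int((~nc["is_colinear"]).sum()) if len(nc) else 0,
            "origins": (nc.loc[~nc["is_colinear"], "origin_mechanism"]
                        .replace("", "no_call").value_counts().to_dict()
                        if len(nc) else {}),
        }

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(_format_report(report))
    return report


def _format_report(r: dict) -> str:
    lines = [f"CNV catalog: {r['n_events']} consensus deletion events"]
    if "size" in r:
        s = r["size"]
        lines.append(
            f"  size mean {s['mean']:.0f} bp, median {s['median']:.0f} bp, "
            f"range {s['min']}-{s['max']} bp")
        lines.append(f"  single-nucleotide breakpoints: "
                     f"{100 * r['precise_fraction']:.1f}%")
    lines.append("polarity (vs. outgroup):")
    for k, v in r.get("polarity", {}).items():
        lines.append(f"  {k}: {v['count']} ({100 * v['fraction']:.1f}%, "
                     f"{v['count']}/{r['n_events']})")
    if "mechanisms" in r:
        lines.append("formation mechanisms:")
        for k, v in sorted(r["mechanisms"].items()):
            lines.append(f"  {k}: {v['count']} ({v['percent']:.2f}%), "
                         f"{v['cumulative_bp']} bp cumulative")
    if "gene_impact" in r:
        gi = r["gene_impact"]
        lines.append(
            f"gene impact: {gi['genes_affected']} genes affected by "
            f"{gi['cnvs_hitting_genes']} CNVs "
            f"(full {gi['full']}, partial CDS {gi['partial_cds']}, "
            f"UTR {gi['utr_only']}, intron {gi['intron_only']})")
    if "sharing" in r:
        for part, d in r["sharing"].items():
            frac = ", ".join(f"{k} {100 * v:.1f}%" for k, v in sorted(d.items()))
            lines.append(f"sharing [{part}]: {frac}")
    if "noncolinear" in r:
        nc = r["noncolinear"]
        lines.append(f"non-co-linear CNV genes: {nc['n_noncolinear']}"
                     f"/{nc['n_cnv_genes']}; origins {nc['origins']}")
    return "\n".join(lines) + "\n"


STAGES = ("simulate", "merge", "polarize", "mechanism", "impact", "origin",
          "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages in order; deterministic for a fixed config."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(asctime)s %(name)s %(message)s")
    outdir = io.ensure_dir(cfg.outdir)
    datadir = io.ensure_dir(os.path.join(outdir, "data"))
    marker = os.path.join(outdir, "FAILED")
    if os.path.exists(marker):
        os.remove(marker)
    stage = ""
    try:
        t0 = time.time()
        stage = "simulate"
        stage_simulate(cfg.sim, datadir)
        stage = "merge"
        stage_merge(datadir, outdir, cfg.merge)
        stage = "polarize"
        stage_polarize(datadir, outdir, cfg.polarize)
        stage = "mechanism"
        stage_mechanism(datadir, outdir, cfg.mechanism)
        stage = "impact"
        stage_impact(datadir, outdir)
        stage = "origin"
        stage_origin(datadir, outdir, cfg.origin, cfg.polarize)
        stage = "report"
        report = write_report(outdir)
        log.info("pipeline done in %.1f s", time.time() - t0)
        return report
    except Exception as exc:
        with open(marker, "w") as fh:
            fh.write(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
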