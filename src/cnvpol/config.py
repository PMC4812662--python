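"""Configuration objects for the simulator and the analysis stages.

All tunable thresholds of the pipeline live here so that every stage is
reproducible from a single YAML file. Defaults encode the study conditions:
a rice-like two-chromosome genome, a ~2%-diverged outgroup, three callers
(paired-end, split-read, read-depth) with their characteristic size biases,
and an 80% insertion polarity among implanted events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

MECHANISMS = ("MEI", "VNTR", "NAHR", "NHR")
CALLERS = ("PE", "SR", "RD")
#: size-class boundaries in bp: [50,500), [500,10k), [10k,inf)
SIZE_CLASSES = ("small", "mid", "large")
SIZE_BOUNDS = (500, 10_000)


class ConfigError(ValueError):
    """A configuration field violates its documented range."""


def size_class(length: int) -> str:
    if length < SIZE_BOUNDS[0]:
        return "small"
    if length < SIZE_BOUNDS[1]:
        return "mid"
    return "large"


def _default_sensitivity() -> dict:
    # PE sees everything; SR is blind above 10 kb (both breakpoints must sit
    # in one read); RD is blind below 500 bp (bin resolution).
    return {
        ("PE", "small"): 0.9, ("PE", "mid"): 0.9, ("PE", "large"): 0.9,
        ("SR", "small"): 0.95, ("SR", "mid"): 0.95, ("SR", "large"): 0.0,
        ("RD", "small"): 0.0, ("RD", "mid"): 0.85, ("RD", "large"): 0.95,
    }


def uniform_sensitivity(p: float) -> dict:
    """Sensitivity table with the same probability in every cell."""
    return {(c, s): p for c in CALLERS for s in SIZE_CLASSES}


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and call-set generator.

    Lengths are bp; probabilities are fractions in [0,1]. ``seed`` drives
    every random draw — identical configs give byte-identical outputs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    gc_content: float = 0.44  # rice-like background GC
    n_genes: int = 120
    n_te_copies: int = 80
    te_library_size: int = 6
    n_vntr_arrays: int = 30
    outgroup_divergence: float = 0.02
    outgroup_indel_rate: float = 0.001  # small 1-3 bp indels per site
    outgroup_gap_rate: float = 1.0  # expected assembly gaps per chromosome
    events_per_mechanism: Mapping[str, int] = field(
        default_factory=lambda: {"MEI": 50, "VNTR": 50, "NAHR": 50, "NHR": 50})
    insertion_fraction: float = 0.8
    n_accessions: int = 12
    caller_sensitivity: Mapping = field(default_factory=_default_sensitivity)
    breakpoint_jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"PE": 50.0, "SR": 0.0, "RD": 0.0})
    false_call_rate: float = 5.0  # false calls per Mb per caller per accession
    rd_bin_size: int = 100  # RD breakpoint resolution; 1 = exact (noise-free)
    duplications_per_origin: Mapping[str, int] = field(default_factory=dict)
    duplication_divergence: float = 0.03  # substitutions between gene copies
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be a positive integer")
        if self.chrom_length < 50_000:
            raise ConfigError("chrom_length must be >= 50000 bp")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must lie in (0,1)")
        for name in ("n_genes", "n_te_copies", "n_vntr_arrays"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.te_library_size < 1:
            raise ConfigError("te_library_size must be positive")
        if not 0.0 <= self.outgroup_divergence <= 0.2:
            raise ConfigError("outgroup_divergence must lie in [0,0.2]")
        if self.outgroup_gap_rate < 0:
            raise ConfigError("outgroup_gap_rate must be non-negative")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ConfigError("insertion_fraction must lie in [0,1]")
        if self.n_accessions < 1:
            raise ConfigError("n_accessions must be a positive integer")
        for mech, n in self.events_per_mechanism.items():
            if mech not in MECHANISMS:
                raise ConfigError(f"events_per_mechanism: unknown mechanism {mech!r}")
            if n < 0:
                raise ConfigError(f"events_per_mechanism[{mech}] must be non-negative")
        for key, p in dict(self.caller_sensitivity).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"caller_sensitivity[{key}] must lie in [0,1]")
        for caller, sd in dict(self.breakpoint_jitter_sd).items():
            if sd < 0:
                raise ConfigError(f"breakpoint_jitter_sd[{caller}] must be non-negative")
        if self.false_call_rate < 0:
            raise ConfigError("false_call_rate must be non-negative")
        for origin in dict(self.duplications_per_origin):
            if origin not in ("TE", "NHEJ", "NAHR"):
                raise ConfigError(f"duplications_per_origin: unknown origin {origin!r}")

    def total_events(self) -> int:
        return sum(self.events_per_mechanism.values())


@dataclass
class MergeParams:
    """Thresholds of the three-step consensus merge."""

    reciprocal_overlap_min: float = 0.5
    min_callers: int = 2
    min_accessions: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.reciprocal_overlap_min <= 1.0:
            raise ConfigError("reciprocal_overlap_min must lie in (0,1]")
        if self.min_callers < 1 or self.min_accessions < 1:
            raise ConfigError("min_callers and min_accessions must be positive")


@dataclass
class PolarizeParams:
    """Thresholds of the outgroup ancestral-state classifier."""

    flank: int = 2000
    max_gap_fraction: float = 0.1  # N-gap cover above which the verdict is undefined
    absent_max: float = 0.2   # aligned fraction below which: insertion
    present_min: float = 0.8  # aligned fraction above which: deletion
    min_flank_aligned: float = 0.5
    probe_min_identity: float = 0.85
    probe_size: int = 300
    max_probes: int = 12
    big_event_size: int = 100_000  # above this, 10 evenly spaced 1-kb probes
    max_anchor_gap: int = 500_000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ConfigError("flank must be non-negative")
        if not self.absent_max < self.present_min:
            raise ConfigError("absent_max must be below present_min")


@dataclass
class MechanismParams:
    """Junction-signature thresholds for mechanism classification."""

    mh_max: int = 10           # NHR: microhomology no longer than this
    nahr_min_len: int = 50     # NAHR: homology at least this long...
    nahr_min_identity: float = 0.9  # ...at at least this identity
    mei_min_fraction: float = 0.8   # MEI: TE cover of the event body
    vntr_period_tolerance: float = 0.1  # |len - k*p| <= tol*p
    homology_scan_window: int = 500

    def __post_init__(self) -> None:
        if self.mh_max >= self.nahr_min_len:
            raise ConfigError("mh_max must be smaller than nahr_min_len")
        if not 0.0 < self.nahr_min_identity <= 1.0:
            raise ConfigError("nahr_min_identity must lie in (0,1]")
        if not 0.0 < self.mei_min_fraction <= 1.0:
            raise ConfigError("mei_min_fraction must lie in (0,1]")


@dataclass
class OriginParams:
    """Thresholds for non-co-linear gene origin inference."""

    min_identity: float = 0.8        # homolog search acceptance
    origin_min_identity: float = 0.9  # only such pairs get an origin call
    te_flank_window: int = 1000
    min_coverage: float = 0.5        # colinearity: exonic probe coverage
    seed_k: int = 16


def _as_tuple_keys(d: Mapping) -> dict:
    """YAML maps use 'PE.small' strings for the (caller, size-class) keys."""
    out = {}
    for k, v in d.items():
        if isinstance(k, str) and "." in k:
            caller, cls = k.split(".", 1)
            out[(caller, cls)] = v
        else:
            out[k] = v
    return out


def sim_config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    if "caller_sensitivity" in d:
        d["caller_sensitivity"] = _as_tuple_keys(d["caller_sensitivity"])
    known = SimConfig.__dataclass_fields__.keys()
    unknown = set(d) - set(known)
    if unknown:
        raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return sim_config_from_dict(data)


def sim_config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["caller_sensitivity"] = {
        f"{c}.{s}": v for (c, s), v in dict(cfg.caller_sensitivity).items()}
    return d
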