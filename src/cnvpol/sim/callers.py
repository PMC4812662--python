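"""Emulate the per-accession call sets of the three CNV callers.

For every truth event, every carrier accession and every caller, a call is
emitted with the (caller, size-class) sensitivity. Split-read (SR) calls
carry exact breakpoints; paired-end (PE) calls are jittered by a rounded
Gaussian; read-depth (RD) calls are snapped outward to ``rd_bin_size``
boundaries (bin size 1 disables snapping — the noise-free limit). False
calls are placed uniformly per caller and accession at ``false_call_rate``
per Mb with sizes resampled from the true size distribution.
"""

from __future__ import annotations

import math
from typing import List

import numpy as np
import pandas as pd

from ..config import CALLERS, SimConfig, size_class
from .events import TruthRecord
from .reference import _rng

CALL_COLUMNS = ["chrom", "start", "end", "caller", "accession"]


def emit_callsets(truth: List[TruthRecord],
                  config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, 4)
    sens = dict(config.caller_sensitivity)
    jitter = dict(config.breakpoint_jitter_sd)
    bin_size = getattr(config, "rd_bin_size", 100)
    chrom_len = config.chrom_length
    rows = []
    for t in sorted(truth, key=lambda t: t.event_id):
        cls = size_class(t.length)
        for acc in sorted(t.carrier_accessions):
            for caller in CALLERS:
                if rng.random() >= sens.get((caller, cls), 0.0):
                    continue
                s, e = t.ref_start, t.ref_end
                if caller == "PE":
                    sd = jitter.get("PE", 0.0)
                    if sd > 0:
                        s = s + int(round(rng.normal(0.0, sd)))
                        e = e + int(round(rng.normal(0.0, sd)))
                elif caller == "RD" and bin_size > 1:
                    s = (s // bin_size) * bin_size
                    e = int(math.ceil(e / bin_size)) * bin_size
                s = max(0, s)
                e = min(chrom_len, max(e, s + 50))
                rows.append((t.chrom, s, e, caller, acc))

    if config.false_call_rate > 0:
        sizes = np.array([t.length for t in truth]) if truth else np.array([1000])
        genome_mb = config.n_chromosomes * chrom_len / 1e6
        chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
        accs = [f"acc{i + 1:02d}" for i in range(config.n_accessions)]
        for acc in accs:
            for caller in CALLERS:
                n_false = rng.poisson(config.false_call_rate * genome_mb)
                for _ in range(n_false):
                    size = int(rng.choice(sizes))
                    size = min(size, chrom_len - 100)
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    s = int(rng.integers(0, chrom_len - size))
                    rows.append((chrom, s, s + size, caller, acc))

    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return df.sort_values(["accession", "caller", "chrom", "start"],
                          kind="stable").reset_index(drop=True)
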