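"""Shared fixtures: simulated datasets reused across the whole suite.

The heavy fixtures are session-scoped; all randomness is seed-pinned so
every run of the suite sees identical data.
"""

from __future__ import annotations

import pytest

from cnvpol.config import SimConfig, uniform_sensitivity
from cnvpol.merge import MergeParams, calls_from_frame, merge_callsets
from cnvpol.polarize import anchors_from_frame, polarize_events
from cnvpol.sim import noise_free_config, simulate_all


@pytest.fixture(scope="session")
def noise_free_sim():
    """Default study fixture under noise-free conditions: 200 events
    (50 per mechanism), 12 accessions, 2 x 1 Mb chromosomes, seed 1."""
    return simulate_all(noise_free_config(seed=1))


@pytest.fixture(scope="session")
def noise_free_events(noise_free_sim):
    return merge_callsets(calls_from_frame(noise_free_sim.calls), MergeParams())


@pytest.fixture(scope="session")
def noise_free_polarized(noise_free_sim, noise_free_events):
    sim = noise_free_sim
    return polarize_events(noise_free_events, sim.pack.genome,
                           sim.out.outgroup, sim.out.gaps,
                           anchors_from_frame(sim.out.anchors))


@pytest.fixture(scope="session")
def noisy_sim():
    """Default noise conditions with uniform per-caller sensitivity 0.9."""
    return simulate_all(
        SimConfig(seed=2, caller_sensitivity=uniform_sensitivity(0.9)))


@pytest.fixture(scope="session")
def noisy_events(noisy_sim):
    return merge_callsets(calls_from_frame(noisy_sim.calls), MergeParams())


@pytest.fixture(scope="session")
def noisy_polarized(noisy_sim, noisy_events):
    sim = noisy_sim
    return polarize_events(noisy_events, sim.pack.genome, sim.out.outgroup,
                           sim.out.gaps, anchors_from_frame(sim.out.anchors))


@pytest.fixture(scope="session")
def dup_sim():
    """Light fixture with ten gene duplications per origin class."""
    cfg = noise_free_config(
        seed=3,
        events_per_mechanism={"MEI": 5, "VNTR": 5, "NAHR": 5, "NHR": 5},
        duplications_per_origin={"TE": 10, "NHEJ": 10, "NAHR": 10})
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast config for determinism/IO tests."""
    return dict(
        n_chromosomes=2, chrom_length=150_000, n_genes=10, n_te_copies=6,
        n_vntr_arrays=4,
        events_per_mechanism={"MEI": 2, "VNTR": 2, "NAHR": 2, "NHR": 2},
        n_accessions=5, seed=17)
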