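"""Shared fixtures: the default synthetic reference, its read index, and a
standard wild-type-like simulated time course reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import dsbseq
from dsbseq import coverage as cov
from dsbseq import metrics

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def genome():
    return dsbseq.build_reference(seed=1)


@pytest.fixture(scope="session")
def index(genome):
    return dsbseq.ExactMatchIndex(genome, k=75)


def simulate_timecourse(genome, index, params, times, seed0):
    """Simulate, emit, map and normalise a full time course.

    Returns a dict with scaled tracks, T0 mask, break-centred profiles,
    population states, mapped pairs and mapping counters per time point.
    """
    analysis = cov.AnalysisConfig()
    tracks, pops, mapped_by, counters_by = {}, {}, {}, {}
    for i, t in enumerate(times):
        pop = dsbseq.simulate_population(params, t, genome)
        reads = dsbseq.emit_read_pairs(pop, genome, params, seed=seed0 + i)
        mapped, counters = dsbseq.map_pairs(
            ((r.read_id, r.mate1, r.mate2) for r in reads), index)
        alns = [a for mp in mapped for a in (mp.aln1, mp.aln2)]
        tracks[t] = cov.per_base_coverage(alns, genome.chromosome_lengths)
        pops[t], mapped_by[t], counters_by[t] = pop, mapped, counters
    scaled = {t: cov.rpgc_scale(tr) for t, tr in tracks.items()}
    t0 = scaled[min(scaled)]
    mask = cov.t0_mask(t0, analysis.t0_threshold)
    profiles = metrics.break_profiles(
        scaled, t0, mask, genome.recipient_name, genome.ho_site, analysis,
        control_region=genome.control_region)
    return {
        "params": params, "tracks": tracks, "scaled": scaled, "mask": mask,
        "profiles": profiles, "pops": pops, "mapped": mapped_by,
        "counters": counters_by, "analysis": analysis,
    }


@pytest.fixture(scope="session")
def wt_run(genome, index):
    """Default wild-type-like scenario at 30x over an 8-point time course."""
    params = dsbseq.SimulationParams(n_cells=1000, depth=30, seed=7)
    return simulate_timecourse(genome, index, params,
                               times=(0, 1, 2, 3, 4, 6, 8, 10), seed0=500)


def read_noise_se(ratio, oracle, depth, bin_size=100, read_length=75):
    """Per-bin standard error of a binned Tx/T0 coverage ratio.

    Models reads overlapping a bin as independent Poisson counts:
    N = depth * (bin + read) / read per unit coverage, for the Tx and T0
    samples separately.
    """
    reads_per_cov = depth * (bin_size + read_length) / read_length
    p = np.maximum(oracle, 0.05)
    v = np.maximum(ratio, 0.05)
    se_emp = np.sqrt(v**2 * (1 / (reads_per_cov * v) + 1 / reads_per_cov))
    se_the = np.sqrt(p * (1 + p) / reads_per_cov)
    return np.maximum(se_emp, se_the)
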