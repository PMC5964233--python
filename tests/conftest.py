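import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scramble_suite as ss
from scramble_suite import sv_caller as sv
from scramble_suite import synthetic_data as sd

settings.register_profile(
    "suite",
    settings(max_examples=25, deadline=None, derandomize=True,
             suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("suite")

SCENARIO_SEED = 20260929


@pytest.fixture(scope="session")
def toy_map():
    """60 kb chromosome, 12 loxPsym sites, 5 essential segments."""
    return ss.random_chromosome(length=60_000, n_sites=12, n_essential=5, seed=11)


@pytest.fixture(scope="session")
def mini_map():
    """Small map without the reporter cassette, for event arithmetic."""
    return ss.random_chromosome(length=30_000, n_sites=6, n_essential=3, seed=5,
                                with_rescues_cassette=False, junction_primers=False)


@pytest.fixture(scope="session")
def roundtrip_bundle():
    """The full desk-scale round-trip study: 500 kb chromosome with 100
    loxPsym sites and 25 essential segments; 20 selected viable outcomes
    (one fixed 5-deletion + 7-inversion scenario) sequenced at 30x with
    200 bp reads and 0.5% substitution error, then run through the complete
    calling pipeline.  Shared by the acceptance tests.
    """
    cmap = ss.random_chromosome(length=500_000, n_sites=100, n_essential=25,
                                seed=SCENARIO_SEED)
    rng = np.random.default_rng(SCENARIO_SEED)
    index = sv.build_index(cmap)
    entries = []
    fixed_types = ["deletion"] * 5 + ["inversion"] * 7
    for i in range(20):
        if i == 0:
            out = sd.simulate_viable_scramble(
                cmap, 12, int(rng.integers(2**31)),
                event_types=fixed_types, condition_on_viability=True)
        else:
            n_ev = 3 + int(rng.integers(10))
            out = sd.simulate_viable_scramble(
                cmap, n_ev, int(rng.integers(2**31)), condition_on_viability=True)
        genome = ss.render_sequence(out.path, cmap)
        reads = sd.simulate_reads(genome, depth=30, read_length=200,
                                  sub_error_rate=0.005,
                                  seed=int(rng.integers(2**31)))
        callset = sv.run_pipeline(cmap, reads, index=index)
        entries.append({"outcome": out, "genome": genome, "callset": callset})
    return {"cmap": cmap, "entries": entries}
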