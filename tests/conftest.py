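"""Shared fixtures: full-scale stage runs and scaled-down cycle configs.

The full-scale stage simulations are cheap (seconds) because speciation
dominates the cost, so the acceptance tests reuse one session-scoped run
of each stage.  The scaled-down configurations (smaller substrate charge
and mineral loading) keep the multi-run property tests (sweeps, tolerance
refinement) inside the suite budget without touching the physics.
"""

import pytest

from phswing.params import load_scenario
from phswing.reactors import (run_cycle, run_oxidation_stage,
                              run_reduction_stage)


@pytest.fixture(scope="session")
def s2o3_oxidation_full():
    """Full-scale thiosulfate-cycle oxidation stage (0.5 M S2O3, 200 g/L
    forsterite at 50 um)."""
    cfg = load_scenario("s2o3_cycle")["oxidation"]
    return run_oxidation_stage(cfg, variant="s2o3")


@pytest.fixture(scope="session")
def s2o3_reduction_full():
    """Full-scale thiosulfate-cycle reduction stage (1.0 M sulfate,
    0.5 M Mg influent)."""
    cfg = load_scenario("s2o3_cycle")["reduction"]
    return run_reduction_stage(cfg, variant="s2o3")


@pytest.fixture(scope="session")
def h2s_reduction_full():
    """Full-scale H2S-cycle reduction stage (0.5 M sulfate / 0.5 M Mg)."""
    cfg = load_scenario("h2s_cycle")["reduction"]
    return run_reduction_stage(cfg, variant="h2s")


@pytest.fixture(scope="session")
def h2s_cycle_full():
    """Complete H2S cycle with the off-gas piped to the oxidation feed."""
    return run_cycle("h2s")


def small_s2o3_config(**overrides):
    """Scaled-down thiosulfate cycle: 1/10 substrate and mineral charge."""
    base = {
        "oxidation": {
            "initial": {"substrate": 0.05, "na": 0.1},
            "minerals": [{"phase": "forsterite", "mass_g_L": 20.0,
                          "radius_m": 50.0e-6}],
            "events": {"t_max_h": 2500.0},
        },
        "reduction": {
            "initial": {"sulfate": 0.1, "mg": 0.05, "na": 0.1},
            "events": {"t_max_h": 1000.0},
        },
    }
    from phswing.params import deep_merge
    return load_scenario("s2o3_cycle", deep_merge(base, overrides))


@pytest.fixture(scope="session")
def s2o3_small_cycle():
    return run_cycle("s2o3", small_s2o3_config())
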