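"""Reactor-level properties: controller contracts, conservation ledgers,
termination events, tolerance robustness, parameter sweeps.

Multi-run tests use the scaled-down thiosulfate cycle (1/10 substrate and
mineral charge) — the conservation and monotonicity properties under test
are scale-free.
"""

import numpy as np
import pytest

from phswing.params import deep_merge, load_scenario
from phswing.reactors import (SolverSettings, StageTimeoutError,
                              run_oxidation_stage, run_reduction_stage,
                              run_validation_scenario, sweep)
from tests.conftest import small_s2o3_config


class TestOxidationStage:
    def test_abiotic_mineral_only_ph_rises(self):
        """No microbes, no substrate: dissolution alone drives pH up
        monotonically from a mildly acidic start."""
        cfg = small_s2o3_config()["oxidation"]
        cfg = deep_merge(cfg, {
            "initial": {"substrate": 0.0, "biomass_mg_L": 0.0,
                        "na": 0.0, "cl": 5e-3},       # HCl-acidified start
            "events": {"t_max_h": 200.0}})
        res = run_oxidation_stage(cfg, variant="s2o3", allow_timeout=True)
        ph = res.series["ph"].to_numpy()
        assert ph[0] < 4.0
        assert np.all(np.diff(ph) > -1e-9)

    def test_no_minerals_ph_falls_monotonically(self):
        """Zero-tailings control: oxidation acid has nothing to neutralise,
        so pH falls monotonically."""
        cfg = small_s2o3_config()["oxidation"]
        cfg = deep_merge(cfg, {"minerals": [], "events": {"t_max_h": 300.0}})
        res = run_oxidation_stage(cfg, variant="s2o3", allow_timeout=True)
        ph = res.series["ph"].to_numpy()
        assert np.all(np.diff(ph) < 1e-9)
        assert ph[-1] < ph[0] - 2.0

    def test_charge_residual_below_tolerance_everywhere(
            self, s2o3_small_cycle):
        for stage in (s2o3_small_cycle.oxidation,
                      s2o3_small_cycle.reduction):
            assert np.all(np.abs(stage.series["charge_residual"]) < 1e-10)

    def test_event_table_deterministic(self):
        cfg = small_s2o3_config()["oxidation"]
        a = run_oxidation_stage(cfg, variant="s2o3")
        b = run_oxidation_stage(cfg, variant="s2o3")
        assert a.events == b.events
        assert a.end_time == b.end_time

    def test_endpoints_invariant_under_halved_tolerances(self):
        """The trajectory is integrator-converged: halving rtol/atol moves
        the sampled states by less than 1e-4 relative."""
        cfg = small_s2o3_config()["oxidation"]
        base = run_oxidation_stage(cfg, variant="s2o3",
                                   solver=SolverSettings())
        tight = run_oxidation_stage(
            cfg, variant="s2o3",
            solver=SolverSettings(rtol=5e-9, atol=5e-11))
        t_common = min(base.end_time, tight.end_time) * 0.95
        for col in ("mg_mol_L", "sulfate_mol_L", "ph", "substrate_mol_L"):
            a = np.interp(t_common, base.series["time_h"], base.series[col])
            b = np.interp(t_common, tight.series["time_h"],
                          tight.series[col])
            assert a == pytest.approx(b, rel=1e-4, abs=1e-8)

    def test_mineral_ledger_consistency(self, s2o3_oxidation_full):
        """Mg in solution matches the shrinking-radius mass ledger."""
        led = s2o3_oxidation_full.ledger
        assert led["mg_released_mol_L"] == pytest.approx(
            led["mg_from_radius_ledger_mol_L"], rel=1e-6)


class TestReductionStage:
    def test_zero_sulfate_no_ph_rise_no_precipitation(self):
        cfg = load_scenario("h2s_cycle")["reduction"]
        cfg = deep_merge(cfg, {"initial": {"sulfate": 0.0, "mg": 0.05,
                                           "cl": 0.1},  # MgCl2 influent
                               "events": {"t_max_h": 50.0}})
        res = run_reduction_stage(cfg, variant="h2s", allow_timeout=True)
        assert res.series["ph"].max() < 8.0
        assert res.summary["precipitated_mol_L"] < 1e-6

    def test_controller_keeps_ph_at_setpoint(self, h2s_reduction_full):
        """pH never exceeds the setpoint plus the controller tolerance
        (0.25 units: stripping of stored sulfide drifts alkalinity after
        the feed cuts off, which the H2 controller cannot actuate)."""
        assert h2s_reduction_full.series["ph"].max() <= 10.0 + 0.25

    def test_captured_co2_never_exceeds_mg_supplied(self,
                                                    h2s_reduction_full):
        s = h2s_reduction_full.series
        mg0 = s["mg_mol_L"].iloc[0] + s["precipitated_mol_L"].iloc[0]
        assert np.all(s["precipitated_mol_L"] <= mg0 + 1e-9)

    def test_elemental_ledgers_closed(self, h2s_reduction_full,
                                      s2o3_reduction_full):
        for res in (h2s_reduction_full, s2o3_reduction_full):
            led = res.ledger
            assert abs(led["sulfur_closure_residual"]) \
                < 1e-6 * led["sulfur_initial_mol_L"]
            assert abs(led["mg_closure_residual"]) \
                < 1e-6 * led["mg_initial_mol_L"]
            assert abs(led["carbon_closure_residual"]) \
                < 1e-6 * max(led["carbon_absorbed_mol_L"], 1e-3)
            assert abs(led["h2_closure_residual"]) \
                < 1e-6 * max(led["h2_fed_mol_L"], 1e-3)

    def test_timeout_raises_with_partial_result(self):
        cfg = load_scenario("h2s_cycle")["reduction"]
        cfg = deep_merge(cfg, {"events": {"t_max_h": 5.0}})
        with pytest.raises(StageTimeoutError) as err:
            run_reduction_stage(cfg, variant="h2s")
        assert err.value.partial.series.shape[0] > 0


class TestCycle:
    def test_sulfur_inventory_closed_across_reactors(self, h2s_cycle_full):
        """S fed to the oxidation reactor = S in sulfate + residual
        substrate + S vented, to 1e-6 relative."""
        led = h2s_cycle_full.oxidation.ledger
        fed = led["sulfur_fed_mol_L"]
        accounted = led["sulfur_in_liquid_mol_L"] \
            + led["sulfur_vented_mol_L"]
        assert accounted == pytest.approx(fed, rel=1e-6)

    def test_h2s_feed_profile_is_reduction_vent(self, h2s_cycle_full):
        """The oxidation reactor's cumulative feed equals the reduction
        reactor's stripped sulfide (the piped off-gas), within the
        interpolation error of the hand-over profile."""
        stripped = h2s_cycle_full.reduction.ledger["sulfur_stripped_mol_L"]
        fed = h2s_cycle_full.oxidation.ledger["sulfur_fed_mol_L"]
        assert fed == pytest.approx(stripped, rel=2e-2)

    def test_cycle_events_monotone_per_reactor(self, h2s_cycle_full):
        ev = h2s_cycle_full.events
        for _, group in ev.groupby("reactor"):
            assert group["time_h"].is_monotonic_increasing


class TestValidationScenario:
    def test_radius_ordering_of_release(self):
        """Cumulative Mg2+ (and Ca2+) at any time is non-increasing in
        particle radius — smaller particles expose more area.

        Checked on the silicate phases only: the carbonate phases are
        solubility-capped, not area-limited, so their dissolved inventory
        legitimately *grows* with radius (large particles keep the solution
        acidic and never reach the saturation cap)."""
        cfg = load_scenario("validation")
        comp = cfg["culture"]["tailings"]["composition"]
        for carbonate in ("calcite", "dolomite"):
            comp["quartz"] += comp.pop(carbonate)
        results = run_validation_scenario(cfg, radii_m=[2.5e-6, 50e-6, 1e-3],
                                          horizon_h=200.0)
        radii = sorted(results)
        times = results[radii[0]].series["time_h"]
        for col in ("mg_mol_L", "ca_mol_L"):
            stacked = np.vstack([
                np.interp(times, results[r].series["time_h"],
                          results[r].series[col]) for r in radii])
            assert np.all(np.diff(stacked, axis=0) <= 1e-12)

    def test_tailings_composition_must_sum_to_one(self):
        cfg = load_scenario("validation")
        cfg["culture"]["tailings"]["composition"]["quartz"] = 0.5
        with pytest.raises(ValueError, match="sum"):
            run_validation_scenario(cfg, radii_m=[50e-6], horizon_h=10.0)


@pytest.fixture(scope="module")
def radius_sweep():
    """Full-scale thiosulfate cycle over three particle radii."""
    return sweep("oxidation.minerals.0.radius_m", [25e-6, 50e-6, 100e-6],
                 variant="s2o3")


class TestSweep:
    def test_radius_leaves_co2_per_cycle_unchanged(self, radius_sweep):
        co2 = radius_sweep["co2_captured_g_L"].to_numpy()
        assert np.ptp(co2) / co2.mean() < 0.01

    def test_cycle_time_monotone_in_radius(self, radius_sweep):
        assert radius_sweep["cycle_time_h"].is_monotonic_increasing

    def test_rpm_speeds_cycle_without_changing_co2(self):
        table = sweep("stirring.rpm", [100.0, 200.0], variant="s2o3")
        co2 = table["co2_captured_g_L"].to_numpy()
        assert np.ptp(co2) / co2.mean() < 0.01
        assert table["cycle_time_h"].iloc[1] < table["cycle_time_h"].iloc[0]

    def test_substrate_sweep_more_co2_longer_cycle(self):
        table = sweep("oxidation.initial.substrate", [0.04, 0.08],
                      variant="s2o3", config=small_s2o3_config())
        assert table["co2_captured_g_L"].is_monotonic_increasing
        assert table["cycle_time_h"].is_monotonic_increasing
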