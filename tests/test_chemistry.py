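"""Speciation, activity and saturation-index tests.

The fast charge-balance solver is checked against an independent in-test
oracle: a brute-force bisection of a *re-derived* charge balance written
with textbook ionization-fraction algebra, sharing no code with the
implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phswing.chemistry import (DAVIES_VALIDITY_CAP, EquilibriumConstantSet,
                               SolutionState, SpeciationError,
                               activity_coefficients, saturation_index,
                               speciate)

K1, K2, KW, KA1 = 10.0 ** -6.35, 10.0 ** -10.33, 1e-14, 10.0 ** -6.98


def bisect_ph_oracle(dic=0.0, sulfide=0.0, sulfate=0.0, thiosulfate=0.0,
                     mg=0.0, ca=0.0, na=0.0, cl=0.0, resolution=1e-6):
    """Ideal-activity charge-balance pH by brute-force bisection.

    Textbook formulation: carbonate/sulfide ionization fractions in [H+],
    bisected over pH in [0, 14] to ``resolution`` pH units.
    """

    def residual(ph):
        h = 10.0 ** -ph
        oh = KW / h
        # ionization fractions of a diprotic acid in terms of [H+]
        d = h * h + h * K1 + K1 * K2
        hco3 = dic * h * K1 / d
        co3 = dic * K1 * K2 / d
        hs = sulfide * KA1 / (h + KA1)
        return (h + 2 * mg + 2 * ca + na
                - oh - hco3 - 2 * co3 - hs - 2 * sulfate
                - 2 * thiosulfate - cl)

    lo, hi = 0.0, 14.0
    assert residual(lo) > 0 > residual(hi)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSpeciate:
    def test_pure_water_is_neutral(self):
        spec = speciate(SolutionState(), ideal=True)
        assert spec.ph == pytest.approx(7.0, abs=1e-6)
        assert spec.h == pytest.approx(spec.oh, rel=1e-6)

    def test_carbonate_equipartition_at_pk1(self):
        """With pH clamped at pK1 (via the mass-action identity), the CO2(aq)
        and HCO3- pools are equal."""
        constants = EquilibriumConstantSet()
        # choose a Na+ background that lands the charge-balance pH at pK1
        target_ph = -math.log10(constants.k1_carbonate)
        dic = 1e-3
        h = 10.0 ** -target_ph
        d = h * h + h * constants.k1_carbonate \
            + constants.k1_carbonate * constants.k2_carbonate
        na = (constants.kw / h - h + dic * h * constants.k1_carbonate / d
              + 2 * dic * constants.k1_carbonate
              * constants.k2_carbonate / d)
        spec = speciate(SolutionState(dic=dic, na=na), ideal=True)
        assert spec.ph == pytest.approx(target_ph, abs=1e-9)
        assert spec.co2_aq == pytest.approx(spec.hco3, rel=1e-9)

    def test_millimolar_bicarbonate_matches_bisection_oracle(self):
        spec = speciate(SolutionState(dic=1e-3, na=1e-3), ideal=True)
        oracle = bisect_ph_oracle(dic=1e-3, na=1e-3)
        assert spec.ph == pytest.approx(oracle, abs=1e-3)

    def test_randomized_totals_match_bisection_oracle(self):
        """Fast solver vs brute-force bisection on 100 random compositions."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            totals = {
                "dic": rng.uniform(0, 0.05), "sulfide": rng.uniform(0, 0.02),
                "sulfate": rng.uniform(0, 0.2),
                "thiosulfate": rng.uniform(0, 0.1),
                "mg": rng.uniform(0, 0.2), "ca": rng.uniform(0, 0.05),
                "na": rng.uniform(0, 0.5), "cl": rng.uniform(0, 0.2),
            }
            spec = speciate(SolutionState(**totals), ideal=True)
            oracle = bisect_ph_oracle(**totals)
            assert spec.ph == pytest.approx(oracle, abs=1e-3), totals

    def test_component_conservation(self):
        spec = speciate(SolutionState(dic=2e-3, sulfide=1e-3, na=3e-3))
        assert spec.co2_aq + spec.hco3 + spec.co3 == pytest.approx(
            2e-3, rel=1e-12)
        assert spec.h2s_aq + spec.hs == pytest.approx(1e-3, rel=1e-12)

    def test_charge_balance_residual_below_tolerance(self):
        for state in (SolutionState(dic=1e-2, na=2e-2),
                      SolutionState(sulfate=0.5, na=0.9, mg=0.05),
                      SolutionState(sulfide=5e-3, na=1e-2)):
            spec = speciate(state)
            assert abs(spec.residual) < 1e-10

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            speciate(SolutionState(dic=-1e-3))

    def test_unbracketed_root_raises_diagnostic(self):
        # 2 mol/L of unneutralised strong-acid anion: pH root below 0
        with pytest.raises(SpeciationError) as err:
            speciate(SolutionState(cl=2.5), ideal=True)
        assert err.value.bracket == (0.0, 14.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(extra_acid=st.floats(1e-6, 0.05), base=st.floats(0.0, 0.05))
    def test_strong_acid_never_raises_ph(self, extra_acid, base):
        s0 = SolutionState(dic=1e-3, na=base + 1e-3)
        s1 = SolutionState(dic=1e-3, na=base + 1e-3, cl=extra_acid)
        assert speciate(s1).ph <= speciate(s0).ph + 1e-9

    def test_idempotent(self):
        state = SolutionState(dic=1e-3, na=2e-3, mg=1e-4)
        a, b = speciate(state), speciate(state)
        assert a.ph == b.ph


class TestActivityCoefficients:
    def test_infinite_dilution_unity(self):
        assert activity_coefficients(0.0, (1, 2, 0)) == [1.0, 1.0, 1.0]

    def test_divalent_below_monovalent(self):
        g1, g2 = activity_coefficients(0.05, (1, 2))
        assert g2 < g1 < 1.0

    def test_davies_closed_form(self):
        i, z = 0.1, 1
        expected = 10.0 ** (-0.509 * z * z
                            * (math.sqrt(i) / (1 + math.sqrt(i)) - 0.3 * i))
        (got,) = activity_coefficients(i, (z,))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_neutral_species_unaffected(self):
        (g0,) = activity_coefficients(0.5, (0,))
        assert g0 == 1.0

    def test_clamped_beyond_validity(self):
        (clamped,) = activity_coefficients(5.0, (2,))
        (at_cap,) = activity_coefficients(DAVIES_VALIDITY_CAP, (2,))
        assert clamped == at_cap

    def test_negative_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            activity_coefficients(-0.1, (1,))


class TestSaturationIndex:
    def test_equilibrium_is_unity(self):
        constants = EquilibriumConstantSet()
        spec = speciate(SolutionState(dic=1e-3, na=2e-3, mg=1e-4))
        omega = saturation_index(spec, constants)
        expected = spec.activities["mg"] * spec.activities["co3"] \
            / constants.ksp_mgco3
        assert omega == pytest.approx(expected, rel=1e-12)

    def test_zero_mg_zero_omega(self):
        spec = speciate(SolutionState(dic=1e-3, na=2e-3))
        assert saturation_index(spec, EquilibriumConstantSet()) == 0.0

    def test_linear_in_mg_activity(self):
        constants = EquilibriumConstantSet()
        s1 = speciate(SolutionState(dic=1e-3, na=2e-3, mg=1e-5), ideal=True)
        s2 = speciate(SolutionState(dic=1e-3, na=2e-3, mg=2e-5), ideal=True)
        # pH shifts slightly; compare at fixed carbonate activity instead
        ratio = (saturation_index(s2, constants) / s2.activities["co3"]) \
            / (saturation_index(s1, constants) / s1.activities["co3"])
        assert ratio == pytest.approx(2.0, rel=1e-9)


def test_ideal_dilute_limit_matches_textbook_closed_form():
    """Open-system carbonate textbook check: pure CO2 solution has
    pH = -log10(sqrt(K1 * [CO2aq])) in the dilute limit."""
    co2 = 1e-5
    # a pure-CO2 solution: DIC fixed, no other ions; [H+] ~ sqrt(K1 CO2aq)
    spec = speciate(SolutionState(dic=co2), ideal=True)
    expected = -0.5 * math.log10(K1 * spec.co2_aq)
    assert spec.ph == pytest.approx(expected, abs=1e-3)
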