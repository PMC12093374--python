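"""Equilibrium speciation of the CO2--H2O--H2S--sulfate--Mg system.

The homogeneous acid/base reactions of the carbonate and sulfide systems are
fast compared with microbial conversion, mineral dissolution, precipitation
and gas--liquid transfer, so they are treated as instantaneous equilibria.
Given the *total* (analytical) concentrations of each dissolved component,
the solution pH is the root of the charge-balance equation; individual
species then follow from mass action.  Activity corrections use the Davies
equation.  Sulfate and thiosulfate are treated as fully dissociated
spectator anions: they enter the charge balance and the ionic strength but
carry no protonation equilibria.

All concentrations are mol L^-1.  The model is isothermal at 25 degC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

log = logging.getLogger(__name__)

#: Debye-Hueckel A parameter at 25 degC (kg^1/2 mol^-1/2).
DEBYE_HUCKEL_A = 0.509

#: Ionic strength (mol L^-1) above which the Davies model is extrapolating;
#: larger values are clamped with a logged warning.
DAVIES_VALIDITY_CAP = 0.7

_warned_clamp = False


class SpeciationError(RuntimeError):
    """Charge-balance root not bracketed / not converged.

    Carries the pH bracketing interval and the residuals at its ends so the
    failure can be diagnosed (e.g. more strong acid than the bracket allows).
    """

    def __init__(self, message, bracket, residuals):
        super().__init__(f"{message} (pH bracket {bracket}, residuals {residuals})")
        self.bracket = bracket
        self.residuals = residuals


@dataclass(frozen=True)
class EquilibriumConstantSet:
    """Thermodynamic constants, all at the reference temperature (25 degC).

    Acidity/solubility constants are on the activity scale; Henry constants
    are mol L^-1 atm^-1.
    """

    k1_carbonate: float = 10.0 ** -6.35   # CO2(aq) + H2O = H+ + HCO3-
    k2_carbonate: float = 10.0 ** -10.33  # HCO3- = H+ + CO3--
    kw: float = 1.0e-14
    ka1_h2s: float = 10.0 ** -6.98        # H2S(aq) = H+ + HS-
    ka2_h2s: float = 10.0 ** -12.9        # HS- = H+ + S-- (off by default)
    ksp_mgco3: float = 10.0 ** -8.03      # magnesite
    ksp_caso4: float = 10.0 ** -4.58      # gypsum (screening check only)
    ksp_calcite: float = 10.0 ** -8.48
    ksp_dolomite: float = 10.0 ** -17.09
    ksp_brucite: float = 10.0 ** -11.16   # Mg(OH)2, monitor only
    henry: dict = field(default_factory=lambda: {
        "co2": 0.0339, "o2": 0.00126, "h2s": 0.102, "h2": 0.00078,
    })
    temperature: float = 298.15

    def __post_init__(self):
        if self.k1_carbonate <= self.k2_carbonate:
            raise ValueError("carbonate K1 must exceed K2")
        if self.ka1_h2s <= self.ka2_h2s:
            raise ValueError("sulfide Ka1 must exceed Ka2")
        for name in ("k1_carbonate", "k2_carbonate", "kw", "ka1_h2s",
                     "ka2_h2s", "ksp_mgco3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SolutionState:
    """Total (analytical) concentrations of the dissolved components.

    ``na``/``cl`` lump the inert background cations and anions of the
    medium.  ``o2`` and ``h2`` are neutral dissolved gases (mol L^-1; any
    mg L^-1 bookkeeping happens at module boundaries).
    """

    dic: float = 0.0        # total CO2(aq) + HCO3- + CO3--
    sulfide: float = 0.0    # total H2S(aq) + HS-
    sulfate: float = 0.0
    thiosulfate: float = 0.0
    mg: float = 0.0
    ca: float = 0.0
    na: float = 0.0
    cl: float = 0.0
    o2: float = 0.0
    h2: float = 0.0
    temperature: float = 298.15
    volume_L: float = 1.0

    _TOTALS = ("dic", "sulfide", "sulfate", "thiosulfate", "mg", "ca",
               "na", "cl", "o2", "h2")

    def validate(self):
        for name in self._TOTALS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"total {name!r} is not finite: {v}")
            if v < 0:
                raise ValueError(f"total {name!r} is negative: {v}")
        if self.volume_L <= 0:
            raise ValueError("liquid volume must be positive")
        return self


@dataclass
class SpeciationResult:
    """Species concentrations and activities satisfying the equilibria."""

    h: float
    oh: float
    co2_aq: float
    hco3: float
    co3: float
    h2s_aq: float
    hs: float
    ph: float
    ionic_strength: float
    gamma: dict        # activity coefficient per species name
    activities: dict   # activity per species name (incl. mg, ca)
    residual: float    # charge-balance residual, mol L^-1


def activity_coefficients(ionic_strength, charges, cap=DAVIES_VALIDITY_CAP):
    """Davies activity coefficients for the given ion charges.

    gamma = 10**(-A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)).  Neutral species
    (z = 0) get exactly 1.  Ionic strengths above ``cap`` are clamped (the
    Davies form is not trustworthy there) and the event is logged.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    i = ionic_strength
    if i > cap:
        global _warned_clamp
        if not _warned_clamp:  # once per process; thereafter at debug level
            log.warning("ionic strength %.3f beyond Davies validity; clamped "
                        "to %.2f (further clamps logged at DEBUG)", i, cap)
            _warned_clamp = True
        else:
            log.debug("ionic strength %.3f clamped to %.2f", i, cap)
        i = cap
    sqrt_i = math.sqrt(i)
    base = DEBYE_HUCKEL_A * (sqrt_i / (1.0 + sqrt_i) - 0.3 * i)
    return [10.0 ** (-base * z * z) for z in charges]


def _ionic_strength_from_species(state, h, oh, hco3, co3, hs):
    pairs = (
        (h, 1), (oh, 1), (hco3, 1), (co3, 2), (hs, 1),
        (state.sulfate, 2), (state.thiosulfate, 2),
        (state.mg, 2), (state.ca, 2), (state.na, 1), (state.cl, 1),
    )
    return 0.5 * sum(c * z * z for c, z in pairs)


def _species_at_ph(state, constants, ph, g1, g2):
    """Mass-action species concentrations at a trial pH.

    ``g1``/``g2`` are the mono- and divalent Davies coefficients; neutral
    species have unit coefficients.  pH is on the activity scale.
    """
    a_h = 10.0 ** (-ph)
    h = a_h / g1
    oh = constants.kw / (a_h * g1)
    # carbonate: K1 = a_H a_HCO3 / a_CO2 ; K2 = a_H a_CO3 / a_HCO3
    f1 = constants.k1_carbonate / (a_h * g1)            # [HCO3]/[CO2aq]
    f2 = f1 * constants.k2_carbonate * g1 / (a_h * g2)  # [CO3]/[CO2aq]
    co2_aq = state.dic / (1.0 + f1 + f2)
    hco3 = co2_aq * f1
    co3 = co2_aq * f2
    fs = constants.ka1_h2s / (a_h * g1)                 # [HS]/[H2Saq]
    h2s_aq = state.sulfide / (1.0 + fs)
    hs = h2s_aq * fs
    return h, oh, co2_aq, hco3, co3, h2s_aq, hs


def _charge_residual(state, constants, ph, g1, g2):
    h, oh, co2_aq, hco3, co3, h2s_aq, hs = _species_at_ph(
        state, constants, ph, g1, g2)
    return (h + 2.0 * state.mg + 2.0 * state.ca + state.na
            - oh - hco3 - 2.0 * co3 - hs
            - 2.0 * state.sulfate - 2.0 * state.thiosulfate - state.cl)


def speciate(state, constants=None, *, ideal=False, ph_bracket=(0.0, 14.0),
             xtol=1e-12, max_gamma_iter=4, ionic_strength_guess=None):
    """Solve the charge balance for pH and return the full speciation.

    The residual (cation charge minus anion charge) is strictly decreasing
    in pH, so a bracketed scalar root-find over ``ph_bracket`` is guaranteed
    to converge whenever the root lies inside the bracket.  Because the
    Davies coefficients depend on the ionic strength, which depends on the
    speciation, the pH solve is wrapped in a short fixed-point loop over the
    ionic strength (converges in 2-3 rounds; charged backgrounds dominate I).

    With ``ideal=True`` all activity coefficients are forced to 1.
    """
    if constants is None:
        constants = EquilibriumConstantSet()
    state.validate()

    if ideal:
        ionic = 0.0
    elif ionic_strength_guess is not None:
        ionic = max(0.0, ionic_strength_guess)
    else:  # background-dominated first guess
        ionic = _ionic_strength_from_species(state, 0.0, 0.0, 0.0, 0.0, 0.0)

    ph = None
    for _ in range(1 if ideal else max_gamma_iter):
        g1, g2 = (1.0, 1.0) if ideal else tuple(
            activity_coefficients(ionic, (1, 2)))
        lo, hi = ph_bracket
        f_lo = _charge_residual(state, constants, lo, g1, g2)
        f_hi = _charge_residual(state, constants, hi, g1, g2)
        if f_lo < 0.0 or f_hi > 0.0:
            raise SpeciationError("charge-balance root not bracketed",
                                  (lo, hi), (f_lo, f_hi))
        new_ph = brentq(lambda p: _charge_residual(state, constants, p, g1, g2),
                        lo, hi, xtol=xtol)
        species = _species_at_ph(state, constants, new_ph, g1, g2)
        h, oh, co2_aq, hco3, co3, h2s_aq, hs = species
        converged = ph is not None and abs(new_ph - ph) < 1e-9
        ph = new_ph
        ionic = _ionic_strength_from_species(state, h, oh, hco3, co3, hs)
        if converged:
            break

    residual = _charge_residual(state, constants, ph, g1, g2)
    gamma = {
        "h": g1, "oh": g1, "hco3": g1, "hs": g1, "na": g1, "cl": g1,
        "co3": g2, "mg": g2, "ca": g2, "sulfate": g2, "thiosulfate": g2,
        "co2_aq": 1.0, "h2s_aq": 1.0,
    }
    activities = {
        "h": h * g1, "oh": oh * g1, "hco3": hco3 * g1, "hs": hs * g1,
        "co3": co3 * g2, "mg": state.mg * g2, "ca": state.ca * g2,
        "sulfate": state.sulfate * g2, "co2_aq": co2_aq, "h2s_aq": h2s_aq,
    }
    return SpeciationResult(
        h=h, oh=oh, co2_aq=co2_aq, hco3=hco3, co3=co3, h2s_aq=h2s_aq, hs=hs,
        ph=ph, ionic_strength=ionic, gamma=gamma, activities=activities,
        residual=residual,
    )


def saturation_index(spec, constants, mineral="magnesite"):
    """Saturation index Omega = ion-activity product / solubility product.

    Omega > 1 means the solution is supersaturated and the mineral can grow;
    Omega = 1 is equilibrium.  Supported minerals: magnesite (MgCO3, the
    carbonation product), calcite, dolomite, brucite, gypsum.
    """
    a = spec.activities
    if mineral == "magnesite":
        return a["mg"] * a["co3"] / constants.ksp_mgco3
    if mineral == "calcite":
        return a["ca"] * a["co3"] / constants.ksp_calcite
    if mineral == "dolomite":
        return a["ca"] * a["mg"] * a["co3"] ** 2 / constants.ksp_dolomite
    if mineral == "brucite":
        return a["mg"] * a["oh"] ** 2 / constants.ksp_brucite
    if mineral == "gypsum":
        return a["ca"] * a["sulfate"] / constants.ksp_caso4
    raise KeyError(f"unknown mineral {mineral!r}")


__all__ = [
    "EquilibriumConstantSet", "SolutionState", "SpeciationResult",
    "SpeciationError", "activity_coefficients", "speciate",
    "saturation_index", "DAVIES_VALIDITY_CAP",
]
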