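"""Gas--liquid mass transfer and well-mixed gas-phase balances.

Interface flux follows the two-film model with a volumetric coefficient:

    J = kLa (C* - C_L),   C* = H y P,                [mol L^-1 h^-1]

positive for absorption.  The sparged head volume is a well-mixed CSTR
whose outlet composition equals the in-vessel composition:

    V_g dC_g/dt = Q (C_g,in - C_g) - J V_L.

At the flow rates of interest (hundreds of m^3 h^-1 through ~0.05 m^3 of
hold-up) the gas residence time is seconds, so the reactor simulations use
the quasi-steady closed form of this balance by default; the dynamic
balance is retained for completeness and testing.

``estimate_kla`` provides a power-input correlation (Rushton power number
-> P/V, then the van't Riet fit) so that impeller-speed sweeps move kLa in
a physically sensible way; unsparged scenarios fall back to a configurable
surface-aeration floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

R_ATM = 0.082057366  # L atm K^-1 mol^-1

#: liquid-phase diffusivities at 25 degC relative to O2 (kLa ~ D^0.5)
DIFFUSIVITY_RATIO = {"o2": 1.0, "co2": 0.915, "h2s": 0.78, "h2": 2.0,
                     "n2": 0.90}


@dataclass
class GasPhaseState:
    """Well-mixed sparged gas phase of one reactor."""

    mole_fractions: dict                 # species -> y (balance is inert)
    pressure: float = 1.0                # atm
    flow_m3_h: float = 360.0             # feed volumetric flow at P, T
    holdup: float = 0.05                 # fractional gas hold-up
    gas_volume_m3: float = 0.05          # effective gas volume
    temperature: float = 298.15

    def __post_init__(self):
        y = self.mole_fractions
        if any(v < 0 for v in y.values()) or sum(y.values()) > 1.0 + 1e-12:
            raise ValueError("mole fractions must be >= 0 and sum <= 1")
        if not 0.0 <= self.holdup < 1.0:
            raise ValueError("hold-up must be in [0, 1)")

    @property
    def molar_flow(self):
        """Total molar gas feed rate, mol h^-1 (ideal gas)."""
        return self.flow_m3_h * 1000.0 * self.pressure \
            / (R_ATM * self.temperature)


@dataclass
class TransferSettings:
    """kLa and Henry constants plus the stirred-tank geometry."""

    kla: dict = field(default_factory=dict)     # species -> h^-1
    henry: dict = field(default_factory=dict)   # species -> mol L^-1 atm^-1
    impeller_diameter: float = 0.376            # m
    impeller_width: float = 0.075               # m
    rotation_rpm: float = 100.0
    reactor_diameter: float = 1.13              # m
    liquid_volume_m3: float = 1.0
    power_number: float = 5.0                   # Rushton turbine
    kla_surface_floor: float = 2.0              # h^-1, unsparged fallback
    # van't Riet coefficients: kLa[s^-1] = c (P/V)^alpha v_s^beta
    vant_riet_c: float = 0.026
    vant_riet_alpha: float = 0.4
    vant_riet_beta: float = 0.5


def interface_flux(species, gas, c_l, settings):
    """Two-film interface flux, mol L^-1 h^-1, absorption positive."""
    y = gas.mole_fractions.get(species, 0.0)
    c_star = settings.henry[species] * y * gas.pressure
    return settings.kla.get(species, 0.0) * (c_star - c_l)


def quasi_steady_mole_fraction(species, y_in, c_l, gas, settings):
    """In-vessel (= outlet) mole fraction from the steady gas balance.

    Solves N (y_in - y) = kLa (H y P - C_L) V_L for y, the quasi-steady
    limit of the CSTR balance.  Clamped at 0 (a species cannot be driven
    to negative partial pressure by stripping of an empty liquid).
    """
    n = gas.molar_flow
    kla = settings.kla.get(species, 0.0)
    h = settings.henry[species]
    v_l = settings.liquid_volume_m3 * 1000.0
    y = (n * y_in + kla * c_l * v_l) / (n + kla * h * gas.pressure * v_l)
    return max(y, 0.0)


def gas_phase_balance(gas, fluxes, liquid_volume_L):
    """Dynamic well-mixed gas balance: d(mole fraction)/dt per species.

    ``fluxes`` maps species -> interface flux (mol L^-1 h^-1, absorption
    positive) evaluated at the *current* in-vessel composition;
    ``gas.mole_fractions`` holds that composition while the inlet enters at
    ``gas.feed_mole_fractions`` if present, else at the current composition
    (pure recirculation).  Total moles in the head volume are held constant
    (isobaric, isothermal; the inert balance absorbs the difference).
    """
    n_total = gas.gas_volume_m3 * 1000.0 * gas.pressure \
        / (R_ATM * gas.temperature)       # mol in the gas space
    n_flow = gas.molar_flow
    feed = getattr(gas, "feed_mole_fractions", gas.mole_fractions)
    derivs = {}
    for species, y in gas.mole_fractions.items():
        y_in = feed.get(species, 0.0)
        transfer = fluxes.get(species, 0.0) * liquid_volume_L
        derivs[species] = (n_flow * (y_in - y) - transfer) / n_total
    return derivs


def estimate_kla(settings, species="o2", gas_flow_m3_h=0.0):
    """kLa estimate from impeller power input, h^-1.

    P = Np rho N^3 D^5 for a Rushton turbine, then the van't Riet
    correlation kLa = c (P/V)^alpha v_s^beta with the superficial gas
    velocity v_s from the sparged flow over the vessel cross-section.
    Species other than O2 are scaled by sqrt of the diffusivity ratio.
    An unsparged vessel (zero gas flow) falls back to the configured
    surface-aeration floor.
    """
    if min(settings.impeller_diameter, settings.reactor_diameter,
           settings.liquid_volume_m3) <= 0 or settings.rotation_rpm <= 0:
        raise ValueError("geometry and speed must be positive")
    scale = math.sqrt(DIFFUSIVITY_RATIO.get(species, 1.0))
    if gas_flow_m3_h <= 0.0:
        return settings.kla_surface_floor * scale
    n_s = settings.rotation_rpm / 60.0
    power = settings.power_number * 1000.0 * n_s ** 3 \
        * settings.impeller_diameter ** 5                  # W (water)
    p_per_v = power / settings.liquid_volume_m3
    cross_section = math.pi * settings.reactor_diameter ** 2 / 4.0
    v_s = gas_flow_m3_h / 3600.0 / cross_section           # m s^-1
    if not 0.002 <= v_s <= 0.3:
        log.warning("superficial velocity %.3g m/s outside correlation "
                    "validity", v_s)
    kla_s = settings.vant_riet_c * p_per_v ** settings.vant_riet_alpha \
        * v_s ** settings.vant_riet_beta                   # s^-1
    return kla_s * 3600.0 * scale


__all__ = [
    "GasPhaseState", "TransferSettings", "interface_flux",
    "quasi_steady_mole_fraction", "gas_phase_balance", "estimate_kla",
    "DIFFUSIVITY_RATIO", "R_ATM",
]
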