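"""Seeded MgCO3 crystal growth.

Precipitation in the reduction reactor is growth on supplied seed crystals
(no nucleation).  The driving force is the magnesite saturation index
Omega = a_Mg a_CO3 / K_sp:

    r_prec = k (Omega - 1)^p   for Omega > 1, else 0   [mol m^-2 h^-1]
    r_cap  = r_prec * A                                 [mol L^-1 h^-1]

with A the total seed surface area per litre.  Seeds are spheres of equal
radius r = sqrt(A / (4 pi n_s)); deposition thickens them at
dr/dt = r_prec M / rho, giving the area growth rate

    r_A = 8 pi n_s r dr/dt = 2 (A / r) dr/dt.

Each mole of MgCO3 removes one mole of Mg2+ and one mole of DIC; the CO2
durably stored is 44.01/84.31 of the precipitated mass.  Undersaturated
seeds do not dissolve (r_prec clamps at 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .stoichiometry import M_MGCO3


@dataclass
class SeedPopulation:
    """MgCO3 seed crystals per litre of liquid.

    Defaults give the 1 m^2 L^-1 initial area with 1 um seeds (seed count
    is a free geometric choice; the initial area is what the model pins).
    """

    count_per_L: float = 1.0 / (4.0 * math.pi * 1.0e-12)  # 1 um seeds
    area_per_L: float = 1.0          # m^2 L^-1
    molar_mass: float = M_MGCO3      # g mol^-1
    density: float = 3.01e6          # g m^-3 (magnesite)
    rate_constant: float = 5.0e-3    # mol m^-2 h^-1
    exponent: float = 1.0            # affinity-law order p
    precipitated: float = 0.0        # cumulative MgCO3, mol L^-1

    def __post_init__(self):
        if self.count_per_L <= 0 or self.area_per_L <= 0:
            raise ValueError("seed count and area must be positive")

    @property
    def seed_radius(self):
        """Per-seed radius implied by the total area, m."""
        return math.sqrt(self.area_per_L / (4.0 * math.pi * self.count_per_L))


@dataclass
class PrecipitationState:
    omega: float
    r_prec: float   # mol m^-2 h^-1
    r_cap: float    # mol L^-1 h^-1
    r_a: float      # m^2 L^-1 h^-1


def precipitation_rate(omega, rate_constant, exponent=1.0):
    """Surface-specific growth rate; zero at or below saturation."""
    if omega < 0:
        raise ValueError("saturation index must be non-negative")
    if omega <= 1.0:
        return 0.0
    return rate_constant * (omega - 1.0) ** exponent


def capture_rate(r_prec, area_per_L):
    """Volumetric CO2 capture rate r_cap = r_prec * A, mol L^-1 h^-1."""
    if area_per_L < 0:
        raise ValueError("seed area must be non-negative")
    return r_prec * area_per_L


def area_growth(seeds, r_prec):
    """Rate of change of the total seed surface area, m^2 L^-1 h^-1."""
    if seeds.area_per_L <= 0:
        raise ValueError("seed area must be positive while growing")
    r = seeds.seed_radius
    dr_dt = r_prec * seeds.molar_mass / seeds.density   # m h^-1
    return 2.0 * (seeds.area_per_L / r) * dr_dt


def evaluate(seeds, omega):
    """Bundle Omega -> (r_prec, r_cap, r_A) for one seed population."""
    r_prec = precipitation_rate(omega, seeds.rate_constant, seeds.exponent)
    return PrecipitationState(
        omega=omega, r_prec=r_prec,
        r_cap=capture_rate(r_prec, seeds.area_per_L),
        r_a=area_growth(seeds, r_prec),
    )


__all__ = [
    "SeedPopulation", "PrecipitationState", "precipitation_rate",
    "capture_rate", "area_growth", "evaluate",
]
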