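"""Shrinking-particle mineral dissolution.

Each mineral phase dissolves with a surface-specific rate

    r_dis = A * exp(-E / (R T)) * a_H+ ** n        [mol m^-2 h^-1]

(a modified Arrhenius law in the proton activity; the forsterite rate used
throughout the cycle simulations is this same law evaluated at 298.15 K).
Particles are monodisperse spheres that shrink without splitting:

    dR_p/dt = -r_dis * M / rho,

so the particle count n_p is constant while the surface area 4 pi R_p^2 n_p
decays with the radius.  Cation release, proton consumption and (for
carbonate phases) DIC release follow the phase's formula-unit stoichiometry,
whose cation charge exactly balances the protons consumed.

Carbonate phases (calcite, dolomite) additionally carry an equilibrium cap:
the printed far-from-equilibrium law would keep dissolving past saturation,
so their rate is scaled by max(0, 1 - Omega) — an affinity-style extension
flagged as such.  Silicates are treated as far from equilibrium always
(the operating regime of the pH swing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from .chemistry import saturation_index

log = logging.getLogger(__name__)

GAS_CONSTANT = 8.314462618  # J K^-1 mol^-1


@dataclass(frozen=True)
class UniversalConstants:
    gas_constant: float = GAS_CONSTANT
    temperature: float = 298.15


@dataclass(frozen=True)
class MineralPhase:
    """Rate-law and stoichiometry parameters of one mineral.

    ``cations`` maps cation name -> moles released per formula unit;
    ``protons`` is the moles of H+ consumed per formula unit and must carry
    the same charge as the released cations.  ``dic_release`` is the moles
    of dissolved inorganic carbon released (carbonates).  ``density`` is in
    g m^-3 (e.g. forsterite 3.27e6).
    """

    name: str
    molar_mass: float           # g mol^-1
    density: float              # g m^-3
    arrhenius_a: float          # mol m^-2 h^-1
    activation_energy: float    # J mol^-1
    order: float                # reaction order n in a_H+
    cations: dict = field(default_factory=dict)
    protons: float = 0.0
    dic_release: float = 0.0
    equilibrium_cap: Optional[str] = None  # chemistry mineral name, or None

    _CHARGES = {"mg": 2, "ca": 2, "na": 1, "k": 1}

    def __post_init__(self):
        if min(self.molar_mass, self.density, self.arrhenius_a) <= 0:
            raise ValueError(f"{self.name}: M, rho and A must be positive")
        if self.order < 0:
            raise ValueError(f"{self.name}: reaction order must be >= 0")
        charge = sum(self._CHARGES[c] * nu for c, nu in self.cations.items())
        if abs(charge - self.protons) > 1e-9:
            raise ValueError(
                f"{self.name}: released cation charge {charge} does not "
                f"balance protons consumed {self.protons}")


@dataclass
class ParticlePopulation:
    """Monodisperse spherical particles of a single phase (per litre)."""

    phase: MineralPhase
    radius: float        # m
    count_per_L: float   # particles per litre of liquid

    def __post_init__(self):
        if self.radius < 0 or self.count_per_L < 0:
            raise ValueError("radius and count must be non-negative")

    @property
    def area_per_L(self):
        """Total particle surface area, m^2 per litre."""
        return 4.0 * math.pi * self.radius ** 2 * self.count_per_L

    @property
    def mass_per_L(self):
        """Remaining particle mass, g per litre."""
        return (4.0 / 3.0) * math.pi * self.radius ** 3 \
            * self.count_per_L * self.phase.density


def particle_count(mass_g_per_L, phase, radius):
    """Initial particle count per litre: n = 3 m / (4 pi rho R^3)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 3.0 * mass_g_per_L / (4.0 * math.pi * phase.density * radius ** 3)


def specific_rate(phase, a_h, temperature=298.15,
                  constants=UniversalConstants()):
    """Surface-specific dissolution rate, mol m^-2 h^-1."""
    if a_h <= 0:
        raise ValueError("proton activity must be positive")
    rt = constants.gas_constant * temperature
    return phase.arrhenius_a * math.exp(-phase.activation_energy / rt) \
        * a_h ** phase.order


@dataclass
class DissolutionRates:
    """Per-phase rate bundle; all chemical rates are mol L^-1 h^-1."""

    cation_rates: dict           # cation name -> release rate
    dic_rate: float              # DIC release (carbonates)
    proton_rate: float           # H+ consumption (positive = consumed)
    radius_rate: float           # dR_p/dt, m h^-1 (<= 0)
    dissolution_rate: float      # formula units dissolved, mol L^-1 h^-1


def population_rates(pop, r_dis):
    """Release/shrinkage rates of one particle population.

    ``r_dis`` is the surface-specific rate from :func:`specific_rate`.
    An exhausted population (R_p <= 0) contributes nothing; the caller is
    expected to clip a marginally negative integrator radius to zero.
    """
    if pop.radius <= 0.0 or pop.count_per_L <= 0.0 or r_dis <= 0.0:
        return DissolutionRates({c: 0.0 for c in pop.phase.cations},
                                0.0, 0.0, 0.0, 0.0)
    area = pop.area_per_L
    formula_rate = r_dis * area   # mol formula units L^-1 h^-1
    phase = pop.phase
    return DissolutionRates(
        cation_rates={c: nu * formula_rate for c, nu in phase.cations.items()},
        dic_rate=phase.dic_release * formula_rate,
        proton_rate=phase.protons * formula_rate,
        radius_rate=-r_dis * phase.molar_mass / phase.density,
        dissolution_rate=formula_rate,
    )


def tailings_rates(populations, speciation, eq_constants,
                   temperature=298.15):
    """Aggregate dissolution of a multi-phase tailings charge.

    Applies the Arrhenius law and shrinking-particle geometry to each phase
    independently (each particle holds one mineral) and sums the Mg2+, Ca2+,
    DIC and proton fluxes.  Carbonate phases are throttled by
    max(0, 1 - Omega) so they never dissolve above saturation.
    Returns (per-phase DissolutionRates list, aggregated totals dict).
    """
    a_h = speciation.activities["h"]
    per_phase = []
    totals = {"mg": 0.0, "ca": 0.0, "na": 0.0, "k": 0.0,
              "dic": 0.0, "protons": 0.0}
    for pop in populations:
        r = specific_rate(pop.phase, a_h, temperature)
        if pop.phase.equilibrium_cap is not None:
            omega = saturation_index(speciation, eq_constants,
                                     pop.phase.equilibrium_cap)
            r *= max(0.0, 1.0 - omega)
        rates = population_rates(pop, r)
        per_phase.append(rates)
        for cation, rate in rates.cation_rates.items():
            totals[cation] += rate
        totals["dic"] += rates.dic_rate
        totals["protons"] += rates.proton_rate
    return per_phase, totals


__all__ = [
    "MineralPhase", "ParticlePopulation", "UniversalConstants",
    "DissolutionRates", "particle_count", "specific_rate",
    "population_rates", "tailings_rates", "GAS_CONSTANT",
]
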