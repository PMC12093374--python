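"""Reaction stoichiometry of the two sulfur cycles.

All coefficients are fixed by the balanced reactions and are independent of
any kinetic parameter — every conversion module pulls its mole ratios from
here so the electron/proton bookkeeping cannot drift between modules.

Oxidation (aerobic, *A. thiooxidans*-type):
    H2S + 2 O2            -> SO4-- + 2 H+
    S2O3-- + 2 O2 + H2O   -> 2 SO4-- + 2 H+
Reduction (anaerobic, *D. vulgaris*-type, H2 as electron donor):
    SO4-- + 4 H2 + 2 H+   -> H2S + 4 H2O
    2 SO4-- + 4 H2 + 2 H+ -> S2O3-- + 5 H2O
Mineral ends of the swing:
    Mg2SiO4 + 4 H+        -> 2 Mg++ + SiO2 + 2 H2O     (forsterite)
    Mg++ + CO3--          -> MgCO3                      (magnesite growth)
"""

from __future__ import annotations

from dataclasses import dataclass

# molar masses, g mol^-1
M_H2S = 34.08
M_S2O3 = 112.13
M_SULFATE = 96.06
M_O2 = 32.00
M_H2 = 2.016
M_CO2 = 44.01
M_MGCO3 = 84.31
M_FORSTERITE = 140.69
M_MG = 24.305


@dataclass(frozen=True)
class OxidationStoichiometry:
    """Per mole of reduced-sulfur substrate oxidized."""

    substrate: str
    molar_mass: float       # g mol^-1 of the substrate
    sulfate_produced: float
    protons_produced: float
    o2_consumed: float
    sulfur_atoms: float     # S atoms per substrate molecule (ledgers)


@dataclass(frozen=True)
class ReductionStoichiometry:
    """Per mole of sulfate reduced."""

    product: str
    h2_consumed: float
    protons_consumed: float
    product_produced: float
    sulfur_atoms_product: float  # S atoms per product molecule


OXIDATION = {
    "h2s": OxidationStoichiometry("h2s", M_H2S, sulfate_produced=1.0,
                                  protons_produced=2.0, o2_consumed=2.0,
                                  sulfur_atoms=1.0),
    "s2o3": OxidationStoichiometry("s2o3", M_S2O3, sulfate_produced=2.0,
                                   protons_produced=2.0, o2_consumed=2.0,
                                   sulfur_atoms=2.0),
}

REDUCTION = {
    # SO4-- + 4 H2 + 2 H+ -> H2S + 4 H2O
    "h2s": ReductionStoichiometry("h2s", h2_consumed=4.0,
                                  protons_consumed=2.0, product_produced=1.0,
                                  sulfur_atoms_product=1.0),
    # 2 SO4-- + 4 H2 + 2 H+ -> S2O3-- + 5 H2O  (per mole sulfate: /2)
    "s2o3": ReductionStoichiometry("s2o3", h2_consumed=2.0,
                                   protons_consumed=1.0, product_produced=0.5,
                                   sulfur_atoms_product=2.0),
}

#: forsterite dissolution: cations released and protons consumed per formula
FORSTERITE_MG_PER_FORMULA = 2.0
FORSTERITE_PROTONS_PER_FORMULA = 4.0

#: MgCO3 precipitation consumes 1 Mg++ and 1 DIC (as CO3--) per formula
MGCO3_MG_PER_FORMULA = 1.0
MGCO3_DIC_PER_FORMULA = 1.0

#: mass of CO2 durably stored per mass of MgCO3 precipitated
CO2_PER_MGCO3_MASS = M_CO2 / M_MGCO3
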