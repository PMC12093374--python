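# Mineral-phase database: modified-Arrhenius rate law r = A exp(-E/RT) aH+^n
# (mol m^-2 h^-1) plus formula-unit stoichiometry.  A values are derived
# from published 25 degC acid-mechanism rate constants k25 (mol m^-2 s^-1)
# via A = 3600 k25 / exp(-E/RT); primary source Palandri & Kharaka (2004)
# unless noted.  Phases marked "placeholder" have approximate constants for
# minerals whose acid kinetics are poorly constrained; all values are
# overridable.  density is g m^-3, molar_mass g mol^-1.
# cations: moles released per formula unit; protons: H+ consumed per formula
# unit (must balance the cation charge); dic_release: DIC from carbonates.
forsterite:          # Mg2SiO4; log k25 = -6.85, E = 67.2 kJ/mol, n = 0.47
  molar_mass: 140.69
  density: 3.27e+6
  arrhenius_a: 3.016e+8
  activation_energy: 67200.0
  order: 0.47
  cations: {mg: 2}
  protons: 4
plagioclase:         # labradorite An60; log k25 = -7.87, E = 42.1, n = 0.626
  molar_mass: 271.8
  density: 2.69e+6
  arrhenius_a: 1.153e+3
  activation_energy: 42100.0
  order: 0.626
  cations: {ca: 0.6, na: 0.4}
  protons: 1.6
clinopyroxene:       # diopside; log k25 = -6.36, E = 96.1, n = 0.71
  molar_mass: 216.55
  density: 3.28e+6
  arrhenius_a: 1.08e+14
  activation_energy: 96100.0
  order: 0.71
  cations: {ca: 1, mg: 1}
  protons: 4
orthopyroxene:       # enstatite; log k25 = -9.02, E = 80.0, n = 0.6
  molar_mass: 100.39
  density: 3.2e+6
  arrhenius_a: 3.57e+8
  activation_energy: 80000.0
  order: 0.6
  cations: {mg: 1}
  protons: 2
serpentine:          # chrysotile; placeholder log k25 ~ -8.5, E ~ 70, n ~ 0.5
  molar_mass: 277.11
  density: 2.53e+6
  arrhenius_a: 2.09e+7
  activation_energy: 70000.0
  order: 0.5
  cations: {mg: 3}
  protons: 6
talc:                # placeholder log k25 ~ -9.5, E ~ 42, n ~ 0.2
  molar_mass: 379.27
  density: 2.75e+6
  arrhenius_a: 26.0
  activation_energy: 42000.0
  order: 0.2
  cations: {mg: 3}
  protons: 6
amphibole:           # tremolite; log k25 = -8.4, E = 18.9, n = 0.7
  molar_mass: 812.37
  density: 2.98e+6
  arrhenius_a: 2.937e-2
  activation_energy: 18900.0
  order: 0.7
  cations: {ca: 2, mg: 5}
  protons: 14
chlorite:            # clinochlore; log k25 = -11.11, E = 88.0, n = 0.5
  molar_mass: 555.80
  density: 2.65e+6
  arrhenius_a: 7.31e+7
  activation_energy: 88000.0
  order: 0.5
  cations: {mg: 5}
  protons: 10
mica:                # phlogopite via muscovite acid law; log k25 = -11.85, E = 22.0, n = 0.37
  molar_mass: 417.26
  density: 2.78e+6
  arrhenius_a: 3.64e-5
  activation_energy: 22000.0
  order: 0.37
  cations: {mg: 3, k: 1}
  protons: 7
quartz:              # effectively inert at 25 degC and pH < 7
  molar_mass: 60.08
  density: 2.65e+6
  arrhenius_a: 1.0e-12
  activation_energy: 0.0
  order: 0.0
  cations: {}
  protons: 0
calcite:             # log k25 = -0.30, E = 14.4, n = 1.0; capped at saturation
  molar_mass: 100.09
  density: 2.71e+6
  arrhenius_a: 6.01e+5
  activation_energy: 14400.0
  order: 1.0
  cations: {ca: 1}
  protons: 2
  dic_release: 1
  equilibrium_cap: calcite
dolomite:            # log k25 = -3.19, E = 36.1, n = 0.5; capped at saturation
  molar_mass: 184.40
  density: 2.84e+6
  arrhenius_a: 4.91e+6
  activation_energy: 36100.0
  order: 0.5
  cations: {ca: 1, mg: 1}
  protons: 4
  dic_release: 2
  equilibrium_cap: dolomite
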