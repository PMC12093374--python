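# Thermodynamic and transport constants, all at 25 degC / 1 atm.
# The model is isothermal; no temperature dependence is applied.
# Every value is overridable through phswing.params.load_constants(overrides=...).
equilibria:
  k1_carbonate: 4.4668e-7    # pK1 = 6.35, CO2(aq)+H2O = H+ + HCO3-  (Stumm & Morgan)
  k2_carbonate: 4.6774e-11   # pK2 = 10.33, HCO3- = H+ + CO3--       (Stumm & Morgan)
  kw: 1.0e-14                # water autoprotolysis, 25 degC
  ka1_h2s: 1.0471e-7         # pKa1 = 6.98, H2S(aq) = H+ + HS-       (Millero)
  ka2_h2s: 1.2589e-13        # pKa2 ~ 12.9 (poorly known; S-- off by default)
  ksp_mgco3: 9.3325e-9       # pKsp = 8.03, magnesite                (Benezeth 2011)
  ksp_caso4: 2.6303e-5       # pKsp = 4.58, gypsum (screening only)
  ksp_calcite: 3.3113e-9     # pKsp = 8.48                           (Plummer & Busenberg)
  ksp_dolomite: 8.1283e-18   # pKsp = 17.09, ordered dolomite
  ksp_brucite: 6.9183e-12    # pKsp = 11.16, Mg(OH)2 (monitor only)
henry:                       # mol L^-1 atm^-1 at 25 degC (Sander 2015 compilation)
  co2: 0.0339
  o2: 0.00126
  h2s: 0.102
  h2: 0.00078
davies:
  debye_huckel_a: 0.509      # kg^0.5 mol^-0.5, 25 degC
  validity_cap: 0.7          # mol L^-1; beyond this the coefficient is clamped
temperature: 298.15
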