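# Tailings-dissolution validation culture: 200 mL static open flask,
# 10 g of mixed mine tailings (~50 um average particle radius), thiosulfate
# growth medium, gas exchange by natural surface diffusion only.
# The tailings phase fractions are a documented placeholder spanning the
# named major phases (the measured composition is not available here).
name: validation
variant: s2o3
temperature: 298.15
culture:
  volume_L: 0.2
  initial:
    substrate: 0.08         # mol L^-1 thiosulfate in the medium
    sulfate: 0.0
    mg: 0.0
    ca: 0.0
    dic: 1.0e-5
    na: 0.2                 # medium background cations (lumped)
    cl: 0.04
    o2: 2.5e-4
    biomass_mg_L: 10.0
  tailings:
    mass_g_L: 50.0          # 10 g in 0.2 L
    radius_m: 50.0e-6
    composition:            # mass fractions, placeholder (sums to 1)
      plagioclase: 0.30
      clinopyroxene: 0.20
      orthopyroxene: 0.10
      serpentine: 0.12
      talc: 0.04
      amphibole: 0.08
      chlorite: 0.05
      mica: 0.04
      quartz: 0.04
      calcite: 0.02
      dolomite: 0.01
  kla_surface: 2.0          # h^-1 (O2 reference), unsparged surface aeration
  horizon_h: 500.0
  radii_m: [2.5e-6, 50.0e-6, 1.0e-3]   # known average and two extremes
organism: validation_oxidizer
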