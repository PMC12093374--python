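# Thiosulfate cycle, 1 m^3 reactors at 25 degC / 1 atm, 100 rpm.
# The reduced sulfur stays aqueous: the completed reduction batch (liquid)
# is transferred to the oxidation reactor, so the two stages couple only
# through batch hand-over, not through a gas line.
name: s2o3_cycle
variant: s2o3
temperature: 298.15
oxidation:
  volume_L: 1000.0
  initial:
    substrate: 0.5          # mol L^-1 thiosulfate charge
    sulfate: 0.0
    mg: 0.0
    ca: 0.0
    dic: 0.0
    na: 1.0                 # counter-cation carried with the thiosulfate
    cl: 0.0
    o2: 2.5e-4
    biomass_mg_L: 50.0
  minerals:
    - {phase: forsterite, mass_g_L: 200.0, radius_m: 50.0e-6}
  gas:
    flow_m3_h: 360.0
    o2: 0.2095
    co2: 420.0e-6
  kla: auto
  events:
    substrate_tol: 1.0e-6
    ph_neutral: 6.5
    t_max_h: 3000.0
reduction:
  volume_L: 1000.0
  initial:
    sulfate: 1.0            # mol L^-1 from the completed oxidation batch
    mg: 0.5
    na: 1.0
    cl: 0.0
    dic: 0.0
    biomass_g_L: 0.1
  h2_feed_mol_L_h: 0.02
  ph_setpoint: 10.0
  ph_deadband: 0.05
  seeds:
    area_m2_L: 1.0
    seed_radius_m: 1.0e-6
    rate_constant: 5.0e-3
    exponent: 1.0
  gas: {flow_m3_h: 360.0, o2: 0.2095, co2: 420.0e-6}
  kla: auto
  events:
    sulfate_tol: 1.0e-5
    omega_done: 1.05
    sustain_h: 1.0
    t_max_h: 2000.0
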