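# Hydrogen sulfide cycle, 1 m^3 reactors at 25 degC / 1 atm, 100 rpm.
# The reduction reactor generates H2S gas which is piped, diluted into the
# 360 m^3/h carrier stream, to the oxidation reactor while being generated.
# Initial charges follow the main-text operating conditions; quantities the
# text does not state (inocula, medium background) are documented defaults.
name: h2s_cycle
variant: h2s
temperature: 298.15
oxidation:
  volume_L: 1000.0
  initial:
    substrate: 0.0          # dissolved sulfide, mol L^-1 (arrives via gas)
    sulfate: 0.0
    mg: 0.0
    ca: 0.0
    dic: 0.0
    na: 0.0
    cl: 0.0
    o2: 2.5e-4              # air-saturated start
    biomass_mg_L: 50.0      # pre-grown inoculum (not stated; default)
  minerals:
    - {phase: forsterite, mass_g_L: 200.0, radius_m: 50.0e-6}
  gas:
    flow_m3_h: 360.0
    o2: 0.2095
    co2: 420.0e-6           # atmospheric CO2 in the carrier air
  kla: auto                 # van't Riet correlation at the stated geometry
  events:
    substrate_tol: 1.0e-6   # mol L^-1 residual substrate
    ph_neutral: 6.5         # stage ends when pH recovers past this
    t_max_h: 3000.0
reduction:
  volume_L: 1000.0
  initial:
    sulfate: 0.5            # mol L^-1 influent from the oxidation side
    mg: 0.5
    na: 0.0
    cl: 0.0
    dic: 0.0
    biomass_g_L: 0.1        # inoculum (not stated; default)
  h2_feed_mol_L_h: 0.02     # dissolved-phase H2 supply cap
  ph_setpoint: 10.0         # H2 feed throttled to keep pH below this
  ph_deadband: 0.05
  seeds:
    area_m2_L: 1.0          # stated initial seed area
    seed_radius_m: 1.0e-6   # geometric choice, sets the seed count
    rate_constant: 5.0e-3   # mol m^-2 h^-1, calibrated (see docs/methods.md)
    exponent: 1.0
  gas: {flow_m3_h: 360.0, o2: 0.2095, co2: 420.0e-6}
  kla: auto
  events:
    sulfate_tol: 1.0e-5
    omega_done: 1.05        # precipitation ends when Omega stays below this
    sustain_h: 1.0
    t_max_h: 2000.0
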