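# Kinetic parameter blocks for the two organisms, version-tagged.
# The published operating description fixes the *form* of both rate laws;
# the numerical values below are literature-plausible defaults chosen once
# (see docs/methods.md) and are overridable per scenario.  Units follow the
# field convention: the oxidizer works in mg L^-1, the reducer in g L^-1
# biomass and mol L^-1 substrates.
oxidizer:            # Acidithiobacillus thiooxidans-type sulfur oxidizer
  version: 1
  mu_max: 0.05       # h^-1; bioreactor default (order of reported values for
                     # growth on thiosulfate; the tailings validation culture
                     # instead uses the calibrated 0.0117 h^-1)
  k_d: 1.0e-3        # h^-1 decay
  k_s: 0.2           # mg L^-1, reduced-sulfur half saturation (sub-mg/L
                     # affinity; calibrated so the H2S cycle reproduces the
                     # reported mass-transfer-limited ~50% absorption)
  k_o: 0.5           # mg L^-1, dissolved-oxygen kinetic constant
  yield_mg_per_mg: 0.05   # mg biomass per mg substrate (chemolithotrophic,
                          # low-yield; Kelly-type energetics)
  maintenance: 0.0   # mg substrate (mg biomass)^-1 h^-1, off by default
  monod_form: product     # dual-Monod product form; "minimum" switchable
reducer:             # Desulfovibrio vulgaris-type sulfate reducer on H2
  version: 1
  mu_max_s: 0.06     # h^-1 maximum growth rate on sulfate/H2
  k_d: 5.0e-4        # h^-1 decay
  k_s_sulfate: 1.0e-3     # mol L^-1 sulfate Monod constant
  k_h: 1.0e-6        # mol L^-1 dissolved-H2 Monod constant
  y_s: 5.0           # g biomass per mol sulfate reduced
validation_oxidizer: # same organism, tailings-culture environment
  version: 1
  mu_max: 0.0117     # h^-1, calibrated against measured growth in the
                     # tailings-dissolution culture
  k_d: 5.0e-4
  k_s: 1.0
  k_o: 0.5
  yield_mg_per_mg: 0.07
  maintenance: 0.0
  monod_form: product
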