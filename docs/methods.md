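# Methods

## Model structure

Each bioreactor is a coupled differential–algebraic system. The slow
processes — microbial growth and conversion, gas–liquid transfer, mineral
dissolution, seeded precipitation — are ODEs in the *total* (analytical)
concentrations of each dissolved component. The fast acid/base chemistry
of the CO₂–H₂O–H₂S system is assumed at equilibrium and eliminated
algebraically inside the ODE right-hand side (index-1 elimination): at
every evaluation the pH is found as the root of the charge-balance
equation and the individual species follow from mass action. The systems
are integrated with a stiff variable-order solver (LSODA via
`scipy.integrate.solve_ivp`; default rtol 1e-8, atol 1e-10) with terminal
events for stage completion.

Writing every reaction charge-balanced over totals makes proton
bookkeeping automatic: oxidizing S₂O₃²⁻ to 2 SO₄²⁻ shifts the anion
charge, and electroneutrality forces the pH down without any explicit
"H⁺ production" state. Conversely forsterite dissolution adds Mg²⁺ and
the pH relaxes up. All elemental ledgers (S, Mg, C, H₂) are integrated as
additional states so that conservation closure is a measured property of
the integration, not an identity.

## Aqueous chemistry

Equilibria at 25 °C only (the model is isothermal; constants in
`data/constants.yaml` with sources): carbonate pK₁ 6.35 / pK₂ 10.33,
sulfide pK_a1 6.98 (S²⁻ negligible below pH 12 and off by default),
K_w 1e-14, magnesite pK_sp 8.03. Sulfate and thiosulfate are fully
dissociated spectator anions: they enter only the charge balance and the
ionic strength. This is the main chemical simplification — at the pH ≈ 1
minimum of the oxidation stage a real sulfate solution holds much of its
sulfate as HSO₄⁻, which would buffer the minimum pH upward; the
stoichiometric endpoints (all acid eventually consumed by the mineral)
are unaffected.

Activity coefficients use the Davies equation (A = 0.509, neutral species
at 1), clamped at I = 0.7 mol L⁻¹ with a logged warning. The oxidation
broth reaches I ≈ 2–3 mol L⁻¹, far beyond any extended Debye–Hückel
model's validity; a Pitzer treatment is out of scope, and the clamp keeps
the correction bounded and monotone. The charge-balance residual is
strictly decreasing in pH, so a bracketed Brent solve on [0, 14] is
guaranteed; the coefficient–ionic-strength circularity is closed by a
short fixed-point loop (2–3 rounds). Residuals at returned states are
below 1e-10 mol L⁻¹ (tested).

## Microbial kinetics

Oxidizer (net growth): dX/dt = μ_max·γ·X − k_d·X with
γ = [C_LS/(K_S+C_LS)]·[C_LO/(K_O+C_LO)]. The product form of the
dual-substrate modifier is the default (a `minimum` form is switchable);
an optional multiplicative hook accepts a lag (Gompertz-type) or pH
window term, default identity. Substrate oxidation is tied to *gross*
growth via the yield; decay does not return substrate; maintenance is off
by default but configurable. Oxygen, sulfate and proton rates follow the
reaction stoichiometry exactly, independent of kinetic parameters
(tested as an electron-balance property).

Reducer: r_X = μ_max,S·X·[S/(K_S+S)]·[C_LH/(K_H+C_LH)],
dX/dt = r_X − k_d·X, r_S = r_X/Y_S; H₂ and proton consumption follow the
reduction stoichiometry (4 H₂ and 2 H⁺ per sulfate to H₂S; per-sulfate
half that to thiosulfate). The reducer's carbon source for biomass is not
modelled, and neither is oxygen toxicity.

Parameter defaults (all in `data/organisms.yaml`, overridable) are
literature-plausible values chosen once: oxidizer μ_max 0.05 h⁻¹,
yield 0.05 mg/mg, K_O 0.5 mg L⁻¹; reducer μ_max,S 0.06 h⁻¹, Y_S 5 g/mol,
K_S 1 mM, K_H 1 µM. Two are calibrated rather than generic: the
oxidizer's K_S (0.2 mg L⁻¹, a sub-mg/L affinity) is set so that the
H₂S-cycle oxidation reactor absorbs ≈ 50 % of the fed H₂S under
mass-transfer limitation, the reported behaviour of that stage; and the
tailings-culture organism block carries the calibrated μ_max of
0.0117 h⁻¹. The stoichiometric endpoints of both cycles are insensitive
to all of these — they move stage *durations* only.

## Mineral dissolution

Surface-specific rate r_dis = A·exp(−E/RT)·a_H⁺ⁿ per phase, evaluated at
298.15 K. Particles are monodisperse spheres, one mineral per particle,
shrinking at dR_p/dt = −r_dis·M/ρ with constant count; area 4πR²n scales
the volumetric release. Forsterite uses the published far-from-equilibrium
olivine acid mechanism (log k₂₅ = −6.85 mol m⁻² s⁻¹, E = 67.2 kJ mol⁻¹,
n = 0.47). With these literature constants the oxidation stage's
dissolution tail runs ≈ 370 h at 50 µm — slower than a calibrated fit
would give, and deliberately left so: the released Mg²⁺ endpoint is fixed
by proton stoichiometry either way, and the constants keep a traceable
provenance.

The tailings database covers the culture's named major phases with
acid-mechanism constants of the Palandri–Kharaka type; serpentine, talc
and mica carry explicitly flagged placeholder values, and the shipped
mass-fraction composition is a documented placeholder (the measured
composition is not available to this package). Carbonate phases (calcite,
dolomite) get the same rate law times max(0, 1 − Ω): the
far-from-equilibrium law alone would dissolve them past saturation. A
consequence worth knowing: the "smaller particles dissolve faster"
monotonicity holds for the silicates (area-limited) but *not* for the
carbonates, which are solubility-limited — at large radius the broth
stays acid and the carbonates dissolve completely, at small radius they
stop at Ω = 1.

In the reactor right-hand side the dissolution rate is ramped linearly to
zero over the final 10 nm of radius. Monodisperse exhaustion is otherwise
a derivative discontinuity that collapses the stiff integrator's step
size; the mass carried by the ramp is (10 nm/R₀)³ of the charge,
many orders below the 1e-6 ledger tolerance.

## Precipitation

Seeded growth only (no nucleation): r_prec = k(Ω − 1)ᵖ for Ω > 1, else 0
(seeds never dissolve); capture r_cap = r_prec·A; spherical seeds of
equal radius give r_A = 2(A/r)·dr/dt with dr/dt = r_prec·M/ρ. Initial
area 1 m² L⁻¹ as specified; the seed count (radius 1 µm) is a geometric
convention, stated in the scenario file. The rate constant
k = 5e-3 mol m⁻² h⁻¹ and the affinity exponent p = 1 are calibration
choices (flagged in the registry) sized so that precipitation tracks the
CO₂ absorption rather than limiting it; p = 2 is configurable. Brucite
(Mg(OH)₂) is not precipitated — the H₂-feed controller holds pH ≤ 10 for
exactly that reason — but a saturation monitor logs a warning whenever
its Ω exceeds 1, which at 0.5 M Mg²⁺ happens already near pH 9 with the
crystalline K_sp used here; the warning is informational.

## Gas–liquid transfer

Two-film fluxes J = k_La(H·y·P − C_L) with Henry constants from the
registry. The sparged head space is a well-mixed CSTR; since its
residence time at 360 m³ h⁻¹ is seconds against hours of process
dynamics, the reactors use the closed-form quasi-steady composition by
default (the dynamic balance is implemented and tested; a config flag
could swap it in). k_La defaults are computed from the van't Riet
power-input correlation (Rushton power number 5) at the stated geometry —
1 m³, 1.13 m vessel, 0.376 m impeller at 100 rpm, 360 m³ h⁻¹ — giving
k_La(O₂) ≈ 233 h⁻¹, scaled to other species by √(D/D_O₂). These values
make H₂S absorption mass-transfer limited at ≈ 50–60 % per pass, matching
the reported behaviour without species-specific tuning. H₂ is fed as a
dissolved-phase term (no H₂ bubble phase), throttled by the pH controller
and by proximity to Henry-law saturation. The unsparged validation
culture uses a surface-aeration floor of 2 h⁻¹ (O₂ reference).

The H₂-feed controller is specified as on/off with a 0.05 pH deadband;
it is implemented as a linear ramp from fully-on at setpoint − 0.05 to
off at the setpoint, the smooth envelope of the relay. Its documented
tolerance is 0.25 pH units: in the H₂S variant, stripping of sulfide
stored in the liquid continues to alkalinise slightly after the feed cuts
off, which no feed controller can counteract.

## Scheduling and termination

The H₂S variant couples the reactors through the gas line: the reduction
stage is simulated first and its vented-H₂S profile (quasi-steady outlet
mole fraction times molar flow) becomes the oxidation reactor's feed
profile in the same 360 m³ h⁻¹ stream. The thiosulfate variant couples by
liquid hand-over of the completed batch. Cycle duration is the longer
stage, since the reactors run concurrently on staggered batches.
Oxidation terminates when residual substrate < 1e-6 mol L⁻¹ *and*
pH ≥ 6.5; reduction when sulfate < 1e-5 mol L⁻¹ *and* Ω < 1.05 sustained
for 1 h of model time. All thresholds are configurable; a stage that
never reaches its event within t_max raises a timeout error carrying the
partial trajectory.

## Synthetic data and calibration

The generator runs the tailings culture at known parameters, samples at a
24 h cadence (500 h default horizon), and applies median-parameterised
multiplicative lognormal noise to biomass/Ca/Mg (positivity, unbiased
median) and additive Gaussian noise to pH, plus optional missingness;
everything is reproducible from the seed. It emulates the *statistical
shape* of batch-culture measurements, not instrument artifacts, and the
underlying trajectory is this package's own model — so recovery tests
demonstrate identifiability of the calibration procedure, not agreement
with the real experiment (whose numerical data are unavailable).
μ_max calibration minimises log-scale least squares (matching the
multiplicative error model) with a bounded scalar optimiser and reports a
profile-objective interval found by root-finding an F-type SSR threshold.
Recovery at 5 % noise is within 5 % of truth (tested); fewer than four
observations or flat data raise a non-identifiability warning.

## Problem sizes used in tests and analyses

Full-scale stage simulations (0.5 mol L⁻¹ sulfur charge, 200 g L⁻¹
forsterite, 1 m³) integrate in about a second each, so the acceptance
checks and sweeps run at full scale. Multi-run property tests
(tolerance-refinement, substrate sweeps) use a 1/10-scale charge, and
calibration round-trips use a 264 h sampling horizon — the properties
under test (conservation, monotonicity, identifiability) are scale-free
choices made for turnaround, not different physics.

## Known limitations

- No HSO₄⁻/bisulfate equilibrium: minimum-pH values in the oxidation
  stage are lower than a full speciation would give.
- Davies activities clamped at I = 0.7 mol L⁻¹; the brines here exceed
  that routinely.
- Monodisperse particles; no PSD evolution, passivation or Fe redox.
- Stage timings depend on the literature/calibrated kinetic defaults and
  are looser than the stoichiometric endpoints; the shipped parameter set
  yields cycles of ≈ 330–370 h.
- Single cycle only; no sulfur make-up loop, no techno-economics.
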