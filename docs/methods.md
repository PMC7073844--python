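# Methods

## Model

`frysim` simulates a potato strip (8.5 × 8.5 mm cross-section, length ≫
width) immersed in hot oil.  Heat enters through the three exposed faces of
the half-width domain [0, W/2] × [0, H] (the fourth face, x = 0, is the
symmetry plane), water diffuses outward and vaporizes inside the strip, and
acrylamide forms and degrades wherever the local temperature allows the
Maillard chemistry to run.

**Heat.**  ρ_e C_p,e ∂T/∂t = ∇·(κ_e ∇T) − R_evp H_evp M_W, with initial
temperature T_i and Robin boundary conditions κ_e ∂T/∂n = h_t (T_bath − T)
on the exposed faces.  The evaporative sink converts the molar vaporization
rate into a volumetric heat sink through the latent heat H_evp (J/kg) and
the molar mass of water M_W (kg/mol).

**Moisture.**  ∂C_w/∂t = ∇·(D_e ∇C_w) − R_evp, with C_w(0) = C_wi and
Robin conditions −D_e ∂C_w/∂n = k_m (C_w − C_eq): the surface relaxes
toward the bath-equilibrium concentration C_eq.  D_e(T) = D₀ exp(−E_a,dif
/ R_g T).

**Evaporation gate.**  R_evp = S_W k_evp C_w, where S_W is a Heaviside
switch at 376.15 K (103 °C).  The gate is what produces the characteristic
core plateau: once a wet region reaches 103 °C the sink consumes whatever
heat arrives, clamping the temperature until the local water is gone.

**Kinetics.**  Reducing sugar → acrylamide → degradation products,
first-order in each step, with shared pre-exponential k₀ and a second
Heaviside gate S_AA at 393.15 K (120 °C):
k₁ = S_AA k₀ exp(−E_a,AA/R_g T), k₂ = S_AA k₀ exp(−E_a,D/R_g T).
Asparagine is assumed non-limiting and is not tracked.  The degraded pool
C_D is bookkeeping that closes C_A + C_AA + C_D = C_Ai exactly.

**Bath schedule.**  T_bath(t) = T_fry for t < t_H, then f·T_fry — the step
factor multiplies the *absolute* temperature, so f = 0.95489 turns a 170 °C
bath into exactly 150.0 °C.  f = 1 recovers constant-temperature frying.

## Effective properties and the crust

Component correlations (quadratic polynomials in °C for density, specific
heat, conductivity of water / carbohydrate / protein) are combined by the
unrenormalized mass-fraction sum Σ value_j ω_j.  Two coefficient sets are
shipped; the `as-printed` default is the set the rest of the model is
calibrated against (its carbohydrate density constant, 159.91 kg/m³, is an
order of magnitude below the textbook Choi–Okos value, but it is the set
consistent with the model's initial water concentration: C_wi·M_W/ρ_e(20 °C)
= 77.3% ≈ the stated 77.2% composition).  The `choi-okos-corrected` set is
available for sensitivity analysis.

By default the *transport* properties track the local water content:
ω_w = C_w·M_W/ρ_e(T_i) with the solid fractions held at their initial
values (0.188 / 0.027) and no renormalization.  Initially this reproduces
the nominal composition; as the crust dries, its conductivity and
volumetric heat capacity collapse toward the sparse solid contribution
(κ_e ≈ 0.06–0.2 W/(m·K)).  That collapsing conductivity is the mechanism
behind the experimentally observed "insulation layer": the surface
decouples from the 103 °C boiling plateau and climbs toward the bath
temperature while the core stays wet and clamped.  With
`update_composition: false` the properties use the fixed initial
composition at local temperature only; in that variant no insulating crust
forms, the surface stays within a few degrees of the plateau for the whole
fry, and the temperature-step schedule suppresses acrylamide almost
completely — qualitatively unlike fried-product data.  The *observables*
(water percent, µg/kg conversion) always use the fixed-composition density,
which pins the 77.2% initial anchor and makes a strip dried to C_eq read
≈21%.

## Discretization

* Uniform node-centred grid, default 35 × 69 nodes (0.125 mm spacing) on
  the half-domain; fields are second-order central differenced in
  conservative finite-volume (flux) form with half control volumes at
  boundaries.  The flux form makes the discrete water-mass and energy
  balances telescope exactly, so the audits recorded in the time series
  close to machine roundoff and genuinely detect any broken balance.
* Time integration: first-order operator splitting per dt = 0.05 s —
  (1) bath temperature, (2) implicit (backward-Euler) heat step with
  properties frozen at step start, (3) implicit moisture step with D_e
  frozen at the updated temperature, (4) exact constant-temperature
  kinetics update at the new nodal temperature.  Both implicit systems are
  symmetric positive definite with bandwidth nx and are solved by banded
  Cholesky (LAPACK `pbsv`), which keeps a full 9-minute run under ~30 s on
  one CPU.
* The gated sinks are evaluated explicitly at step-start fields.  At
  dt = 0.05 s the explicit gate produces a bounded chatter of ~0.2 K around
  the 103 °C plateau; the kinetics update is exact and therefore entirely
  insensitive to dt (composing 10³ steps matches the closed-form
  series-reaction solution to <10⁻¹² relative).
* Gates are sharp Heaviside functions by default; `gate_smoothing_K`
  replaces them with a linear ramp of the given width for sensitivity
  studies.
* Moisture concentrations are clipped at zero (the clipped mass is logged
  and enters the audit); in practice the implicit M-matrix step keeps the
  field positive and the clipped mass is zero.

Convergence: doubling the resolution in both directions (69 × 137,
dt = 0.025 s) or halving it (18 × 35, dt = 0.1 s) changes the headline
observables of the 9-minute constant-bath run (final water %, final average
acrylamide, final surface temperature) by less than 0.4%.

## Parameters

All defaults are the published input-parameter set for this strip; the
most influential are:

| symbol | default | units | role |
|---|---|---|---|
| h_t | 105 | W/(m²·K) | oil-side heat transfer; sets the early heating rate |
| k_evp | 8.0·10⁻³ | 1/s | evaporation rate above 103 °C; sets drying speed and plateau stiffness |
| H_evp | 2.3·10⁶ | J/kg | latent heat; converts drying into heat demand |
| k_m, C_eq | 5.2·10⁻⁴, 9265 | m/s, mol/m³ | surface moisture exchange and its floor |
| D₀, E_a,dif | 5.0·10⁻⁶, 27.6·10³ | m²/s, J/mol | liquid-water diffusivity (Arrhenius) |
| k₀, E_a,AA, E_a,D | 22, 44.5·10³, 21.3·10³ | 1/s, J/mol | acrylamide formation/degradation |
| M_A | 0.172 | kg/mol | single multiplicative mol→µg/kg conversion for acrylamide |

M_W = 0.018015 kg/mol and R_g = 8.314 J/(mol·K) are standard constants.
T_i = 293.15 K is a plain default.  Activation energies are stored in
J/mol; configs may supply kJ/mol via `energy_units: kJ/mol`.

M_A deserves a note: it is fixed as the mol→kg conversion constant in the
acrylamide observable (1 × 10⁹ · C_AA · M_A / ρ_e) and nowhere else.  It does
not equal acrylamide's molar mass (0.071 kg/mol); since it is a single
multiplicative constant, any reinterpretation would rescale every
acrylamide output uniformly.

## Conventions pinned by internal anchors

* Average water percent = 100·⟨C_w⟩·M_W / ⟨ρ_e(T)⟩ (ratio of area-weighted
  means).  This reproduces the 77.2% initial composition and the ≈21%
  equilibrium floor.  Because the denominator falls as the strip heats, the
  percent can rise by a few hundredths of a point during early heating even
  though the water inventory strictly decreases; the monotonicity audit
  allows 0.05 points of slack for this.
* The "surface" probe is the lateral-face midpoint (x = W/2, y = H/2), not
  the corner: the corner is the field maximum and runs hotter than the
  reported surface trace.  The "core" probe is the strip centre.
* The acrylamide lag time is measured with a 1 µg/kg detection threshold —
  the resolution limit of a trajectory plotted on a 0–450 µg/kg axis;
  strictly-first-nonzero would report the first floating-point crumb at a
  single corner node.

## Known limitations

* No volume shrinkage, oil uptake, pressure-driven vapor transport, or
  browning chemistry; the oil bath is an infinite reservoir at the
  scheduled temperature.
* The Robin moisture condition is two-way: a surface node drier than C_eq
  draws water back from the bath.  This is what the governing equations
  prescribe, and the crust floor it produces is consistent with the
  equilibrium-floor behaviour of fried products, but it is not a physical
  description of an oil interface.
* The evaporation and kinetics gates are sharp switches at 103 °C / 120 °C;
  real vaporization and Maillard onset are gradual.
* First-order splitting and frozen-coefficient implicit steps are
  formally O(dt); dt = 0.05 s puts the splitting error well below the model
  uncertainty (halving dt moves observables <0.1%).
* The simulator reproduces the temperature-step (TSFA) frying results of
  the underlying study closely; for constant-temperature frying it yields a
  somewhat wetter, cooler, higher-acrylamide strip than the study's
  validation figures (e.g. 31% vs 25% final water).  The constant-bath and
  TSFA figures of that study cannot both be matched by any single member of
  this model family (see the water/energy budget: a hotter surface requires
  the crust to stop evaporating, which simultaneously retains more water),
  so the package pins its defaults to the variant that matches the TSFA
  predictions and the documented insulation-layer mechanism.
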