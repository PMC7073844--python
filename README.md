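# frysim

Deterministic simulator of deep-fat frying of French-fry strips, coupling
two-dimensional heat conduction, moisture diffusion with gated evaporation,
and acrylamide reaction kinetics — built to study **temperature-step
frying** (dropping the oil temperature partway through the fry) as a
mitigation strategy for acrylamide, a Group 2A probable carcinogen formed
by the Maillard reaction in starchy food above ~120 °C.

It is aimed at food-process engineers and researchers who want to ask
questions like *"how much acrylamide do I avoid if I fry at 170 °C for
3 minutes and finish at 150 °C, and is the product still fried?"* without
a commercial finite-element license.

## Model in brief

On the half cross-section [0, W/2] × [0, H] of an 8.5 × 8.5 mm strip
(symmetry plane at x = 0, convective oil contact elsewhere):

- **heat:** ρ_e C_p,e ∂T/∂t = ∇·(κ_e ∇T) − R_evp H_evp M_W,  with
  κ_e ∂T/∂n = h_t (T_bath − T) at the surface,
- **moisture:** ∂C_w/∂t = ∇·(D_e ∇C_w) − R_evp,  with
  −D_e ∂C_w/∂n = k_m (C_w − C_eq),
- **evaporation:** R_evp = S_W k_evp C_w, gated on at T ≥ 103 °C — this
  clamps wet regions at the boiling plateau,
- **kinetics:** A →k₁ AA →k₂ D (reducing sugar → acrylamide → degraded
  products), k_i = S_AA k₀ exp(−E_a,i/R_g T), gated on at T ≥ 120 °C,
- **schedule:** T_bath = T_fry until t_H, then f·T_fry on the absolute
  scale (f = 0.95489 maps 170 °C to exactly 150.0 °C); f = 1 is ordinary
  constant-temperature frying.

Effective properties are mass-fraction mixtures of temperature-dependent
water/carbohydrate/protein correlations; by default the water fraction
tracks the local water concentration, so a drying crust becomes a thermal
insulator and the surface decouples from the 103 °C plateau — the
"insulation layer" regime seen in real frying.  See `docs/methods.md` for
the full account, all parameter defaults, and numerical choices.

## Worked example

Compare 9 minutes of constant 170 °C frying against the 3-minute
temperature-step schedule:

```bash
frysim compare \
    src/frysim/configs/paper_170C.yaml \
    src/frysim/configs/paper_tsfa3.yaml \
    --out compare_out
```

prints (abridged):

```json
{
  "A": {
    "final_water_pct": 30.72,
    "final_aa_ugkg": 542.2,
    "T_surface_C": 134.67,
    "T_range_C": [102.97, 153.52]
  },
  "B": {
    "final_water_pct": 36.95,
    "final_aa_ugkg": 175.0,
    "T_surface_C": 120.97,
    "T_range_C": [102.94, 135.71]
  },
  "acrylamide_reduction_pct": 67.7
}
```

Reading: the constant fry ends at 30.7% water with 542 µg/kg average
acrylamide and a 135 °C surface (hot spots to 154 °C at the corners, core
clamped at 103 °C).  Stepping down to 150 °C after 3 minutes ends wetter
(37.0%), cooler (nothing above 136 °C), and with 68% less acrylamide —
175 µg/kg, comfortably under the 500–600 µg/kg guideline for the product
class — at the cost of a few percent more residual moisture.

The same library surface is available from Python:

```python
from frysim import ModelParameters, FryingSchedule, NumericsConfig, simulate

p = ModelParameters()                       # published strip parameters
s = FryingSchedule(T_fry=443.15, t_H=180.0, f=0.95489, t_end=540.0)
result = simulate(p, s, NumericsConfig(snapshot_times=(540.0,)))
print(result.series.to_dataframe().tail(1))
```

`frysim run --config ... --out ...` writes the trajectory CSV, snapshot
CSVs, and a manifest that reruns the simulation bit-identically;
`frysim audit --config ...` re-checks the built-in conservation audits
(water mass and energy close to machine roundoff by construction of the
finite-volume scheme).

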