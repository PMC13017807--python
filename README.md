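# leafosc

Optimal stomatal conductance modelling of leaf gas exchange, built around
the citrus parameterisation. The package provides:

- **`leafosc.biochem`** — two-branch C3 assimilation kinetics
  (carboxylation- vs electron-transport-limited) with peaked-Arrhenius
  temperature corrections, infinite mesophyll conductance.
- **`leafosc.calibration`** — nonlinear least-squares fitting of
  `Vcmax25`, `Jmax25`, `Rd25` (optionally per-curve `Km`, `Γ*`) from A-ci
  response curves, with 25 °C normalisation and cross-curve averaging.
- **`leafosc.marginal_cost`** — analytic point-wise estimation of the
  marginal water cost of carbon gain λ = ∂E/∂A from gas-exchange records,
  with limitation tagging and 10–90 % trimmed-median daily / long-term
  characteristic values. Citrus characteristic constants ship as
  `CITRUS_LAMBDA_CO` (1787.10), `CITRUS_LAMBDA_VC` (1478.51) and
  `CITRUS_LAMBDA_VJ` (2703.65) mol·mol⁻¹.
- **`leafosc.oscm`** — the coupled solvers (single-branch `OSCvc`/`OSCvj`
  and combined `OSC` forms; long-term or daily λ schedules) predicting
  `ci`, `A`, `gs`, `E` from meteorology and a prescribed λ, with a
  0.01 mol·m⁻²·s⁻¹ minimum-conductance floor.
- **`leafosc.evaluation`** — R²/MAE/MBE/|RE| scoring, binned |RE| error
  surfaces, and one-factor-at-a-time perturbation sensitivity
  coefficients.
- **`leafosc.synthetic_data`** — deterministic generators for
  meteorology, forward-modelled gas exchange with known λ, and A-ci
  curves with known traits.
- **`leafosc.interface`** — CSV readers/writers, YAML run configuration,
  bundled reference tables (`leafosc.data`), and the CLI.

## CLI

```bash
# generate a synthetic gas-exchange dataset at a known lambda
leafosc synth gasex --n-days 3 --points-per-day 40 --out gx.csv

# estimate lambda and its trimmed-median characteristic values
leafosc lambda --input gx.csv --trim 10,90 --out lam

# forward simulation with the combined form and a long-term lambda
leafosc synth meteo --n-days 1 --points-per-day 20 --out met.csv
leafosc simulate --form combined --lambda 1787.10 --meteo met.csv --out pred.csv

# fit traits from an A-ci curve file
leafosc synth aci --out aci.csv
leafosc calibrate --input aci.csv --out fit.csv

# score predictions and probe sensitivity
leafosc evaluate --pred pred.csv --obs gx.csv --vars gs,A --out report
leafosc sensitivity --form vc --factors Ta,D,lambda,Vcmax25 --out sc.csv
```

All subcommands accept `--config cfg.yaml` (species parameters, λ
defaults, trim bounds, seed) and `--seed`.

## Conventions

Units follow portable photosynthesis-system exports: `A` in
μmol·m⁻²·s⁻¹, `E` in mmol·m⁻²·s⁻¹, `gs` in mol·m⁻²·s⁻¹, CO2 mole
fractions in μmol·mol⁻¹, `D`/`P` in kPa, λ in mol H₂O · mol CO₂⁻¹.
Temperature-response functions use a 298 K reference exactly as the
constants were published, while Kelvin leaf temperature is `Tl + 273.15`.
CSV schemas are documented in `leafosc/interface/io.py`.
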