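# thermowire

Fast PRFS MR thermometry and semi-empirical prediction of RF-induced
heating near implanted wires.

Conductive leads (abandoned pacemaker leads, DBS electrodes, guidewires)
can couple to the MRI transmit field and heat the tissue at their tip.
Scanner-reported exposure metrics — SAR, B₁⁺rms, total emitted energy —
are time averages and do not predict the *maximal* temperature reached at
a wire tip, which depends on how fast energy is deposited relative to
local thermal diffusion. `thermowire` implements both halves of a
measurement-based safety workflow:

1. **Thermometry reconstruction** — proton-resonance-frequency-shift
   (PRFS) temperature mapping from dynamic phase-image series
   (ΔT = Δφ / (2π·γ·B₀·c·TE), c ≈ −0.0094 ppm/°C), with background
   drift correction and a causal first-order Butterworth temporal
   low-pass (0.04 Hz) that brings per-pixel precision from ≈ 0.65 °C to
   ≈ 0.21 °C at a 3-sample latency.
2. **Heating calibration and prediction** — the temperature at the
   hottest point near the tip, for a spatially Gaussian heat source
   driven at constant power P₀ between t₀ and t₁, follows a
   piecewise-logarithmic law

   ```
   T(t) = 0                                   t ≤ t₀
   T(t) = αP₀τ · ln((t−t₀+τ)/τ)               t₀ ≤ t ≤ t₁
   T(t) = αP₀τ · ln((t−t₀+τ)/(t−t₁+τ))        t ≥ t₁
   ```

   with absorption coefficient α (°C·W⁻¹·s⁻¹) and time constant τ (s).
   Fitting (α, τ) to hottest-pixel heating curves acquired at several
   calibration powers and describing α(P), τ(P) by second-order
   polynomials yields the maximal temperature rise of *any* sequence
   from its effective emitted power (energy/duration) and duration,
   including isotherm charts over the (power, duration) plane.

A synthetic-acquisition module generates complex image series, probe
channels and calibration datasets with known ground truth, so the entire
pipeline is testable without scanner data.

## Worked example

```python
import numpy as np
import thermowire as tw
from thermowire.io import load_wire_calibration

# 1. calibration-curve coefficients from the shipped copper-wire table
df = load_wire_calibration()
b1 = tw.fit_beta(df["fa_deg"],   df["tmax_C"], model="quadratic")
b2 = tw.fit_beta(df["b1rms_uT"], df["tmax_C"], model="quadratic")
print(f"beta1 = {b1.beta:.2e} C/deg^2  (R^2 = {b1.r_squared:.3f})")
print(f"beta2 = {b2.beta:.3f} C/uT^2   (R^2 = {b2.r_squared:.3f})")

# 2. simulate a heating experiment and reconstruct it
params = tw.EqOneParams(alpha=0.02, tau=10.0, p0=30.0)
window = tw.HeatingWindow(10.0, 90.0)
truth  = tw.simulate_temperature_field(tw.PhantomSpec(), params, window,
                                       np.arange(120.0))
series = tw.simulate_complex_series(truth, noise=tw.NoiseDriftSpec(seed=42))
dT   = tw.TemperatureReconstructor().fit_transform(series)
dT_f = tw.lowpass_filter(dT)
hot  = tw.hottest_pixel(dT_f, end_window=(86, 90))
print(f"hottest pixel {hot.index}: {hot.mean:.2f} +/- {hot.std:.2f} C")

# 3. fit the heating model to the reconstructed hottest-pixel curve
fit = tw.fit_eq1(dT.times, dT.pixel_curve(hot.index), window, p0=params.p0)
print(f"alpha = {fit.alpha:.4f} (truth 0.0200), tau = {fit.tau:.1f} s (truth 10.0)")
```

prints

```
beta1 = 4.29e-03 C/deg^2  (R^2 = 0.984)
beta2 = 2.004 C/uT^2   (R^2 = 0.985)
hottest pixel (0, 24, 24): 13.43 +/- 0.23 C
alpha = 0.0210 (truth 0.0200), tau = 9.8 s (truth 10.0)
```

The β coefficients quantify the quadratic growth of the end-of-heating
peak rise with heating-module flip angle and with B₁⁺rms. The hottest
pixel lands on the simulated hotspot center and its end-of-heating mean
(13.43 °C, filtered) sits close to the analytic peak (13.18 °C) — the
small excess is filtered noise at the argmax. The nonlinear fit recovers
the truth (α, τ) within a few percent under the pipeline's realistic
noise level.

A command-line interface mirrors the workflow:

```bash
thermowire simulate    --out-dir run/ --seed 1
thermowire reconstruct --mag run/mag.nii.gz --phase run/phase.nii.gz \
                       --sidecar run/series.json --out-dir run/recon
thermowire calibrate   --curves-index curves.csv --out-dir cal/
thermowire predict     --model cal/calibration.json --sequence cine:43.59:9 \
                       --grid-powers 1:50:50 --grid-durations 5:300:60 \
                       --out-dir pred/
```

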