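# Methods

## PRFS reconstruction

Temperature change is mapped from the phase of a dynamic gradient-echo
series: the water proton resonance frequency shifts by c = −0.0094 ppm/°C,
so at echo time TE and field B₀ the phase changes by
2π·γ·B₀·c·TE radians per °C (−0.0679 rad/°C at TE = 18 ms, B₀ = 1.5 T,
the default operating point). The first `n_reference` dynamics
(default 10) are averaged **as complex numbers** and the argument of the
mean taken as the reference phase; an arithmetic mean of phases would be
biased at the ±π wrap. Each dynamic's phase difference against the
reference is computed through the complex product, which wraps it to
(−π, π] automatically; no spatial unwrapping is performed — the method
tracks temperature incrementally, as real-time pipelines do, and assumes
the per-dynamic phase change stays below π (ΔT steps below ≈ 46 °C per
dynamic, far above anything physical here).

### Drift correction

Scanner frequency drift and slowly varying background fields contaminate
the phase. Per dynamic and slice, a spatial polynomial (default order 0,
i.e. a scalar offset; order configurable) is fit by least squares to the
temperature map over a user-supplied background mask that excludes the
heated region. The fitted coefficients are smoothed with a **trailing**
moving average over the last 10 dynamics (causal, so usable online) and
the resulting background field is subtracted from all pixels. A
drift-free series passes through unchanged to < 1e−10 °C. The trailing
window lags a linear drift by (window−1)/2 samples, leaving a residual
of slope × 4.5 dynamics; with realistic drift rates this stays well
below the filter noise floor.

### Temporal filtering

A first-order Butterworth low-pass (cutoff 0.04 Hz at 1 Hz sampling) is
applied causally, single-pass, pixel by pixel, with the filter state
initialised to the first sample (no start-up transient; DC gain exactly
1). A causal filter is the only choice consistent with online use and
carries latency: we define `lag_samples` as the step-response half-rise
time, the smallest n at which the unit-step response reaches 0.5 — this
gives 3 samples for the default design and is the lag compensated before
RMSE comparisons against a probe. (The DC group delay, 3.96 samples,
overstates the perceived latency of the rising edge.) For white noise
the equivalent-noise-bandwidth argument predicts a std reduction factor
√(f_c·π/2 / (f_s/2)) ≈ 0.354, i.e. 0.65 °C → ≈ 0.21 °C.

### Statistics

Precision maps are per-pixel temporal mean μ_T and standard deviation
σ_T (ddof = 1) over all dynamics. ROI summaries use the five-number
box-and-whisker convention (minimum, Q1, median, Q3, 95th percentile)
with linear interpolation between order statistics. The hottest pixel is
the argmax of the mean ΔT over the end-of-heating window (default
dynamics 86–90 inclusive), ties broken by the first pixel in row-major
order. Hotspot width is the linearly interpolated full width at half
maximum of the 1-D profile through the hotspot.

## Heating model

A wire tip heated by RF-induced currents behaves as a compact,
approximately Gaussian heat source. For constant power P₀ deposited
between t₀ and t₁, the hottest-point temperature follows the
piecewise-logarithmic law given in the README: zero before t₀,
αP₀τ·ln((t−t₀+τ)/τ) while heating, αP₀τ·ln((t−t₀+τ)/(t−t₁+τ)) while
cooling. It is continuous at both edges, strictly increasing during
heating, strictly decreasing after, and decays to zero. The peak is
αP₀τ·ln((Δt+τ)/τ) at t = t₁. α (units °C·W⁻¹·s⁻¹, so that αP₀τ is °C)
lumps the coupling of the sequence's RF field into the wire; τ reflects
the source size and local thermal diffusivity.

### Fitting

(α, τ) are estimated by bounded nonlinear least squares (α ≥ 0, τ > 0;
Levenberg–Marquardt via trust-region reflective). Initialisation:
τ₀ = 10 % of the heating duration, α₀ from the observed curve maximum
through the closed-form peak; on non-convergence the fit restarts from
5 log-spaced τ₀ values between 1 % and 100 % of the heating duration.
The procedure is deterministic. Curves with no detectable heating
(α̂ within 2 standard errors of 0, or P₀ = 0, where α is structurally
unidentifiable) are flagged `low_signal` and excluded from the power
polynomials rather than rejected. On noiseless curves the fit recovers
the generating parameters to ≥ 6 significant digits; at the pipeline's
filtered precision (≈ 0.2 °C) both parameters are recovered within 5 %
in ≥ 90 % of replicates on 120-sample curves.

### Calibration and prediction

α_i and τ_i from calibration curves at powers P_i are fit with
second-order polynomials in P (≥ 3 distinct usable powers required).
Predicting a sequence reduces it to its effective emitted power
P = E/duration and its duration: α(P), τ(P) are evaluated, the heating
window is (0, duration), and the peak is the closed form at t = t₁.
Negative α(P) or non-positive τ(P) raise an out-of-domain error — the
model **refuses** rather than clips, because quadratics behave
arbitrarily outside their fit range; powers outside the calibrated range
are allowed but flagged `extrapolated`. P = 0 predicts 0 identically.
Isotherm grids evaluate the scalar prediction on a (power, duration)
lattice, with out-of-domain cells masked as NaN; they chart acceptable
exposure conditions for arbitrary sequences.

### Calibration-curve coefficients

The end-of-heating peak rise grows quadratically with heating-module
flip angle and with B₁⁺rms (RF power ∝ B₁² ∝ FA²) and linearly with
emitted energy. The quadratic fits are **origin-constrained**
(T = βx²) by default: physically there is no heating at zero exposure,
and this convention reproduces the measured wire table's coefficients
(β₁ = 4.29×10⁻³ °C/deg², β₂ = 2.004 °C/μT², both R² ≈ 0.98, via the
closed form Σx²T/Σx⁴). An unconstrained option (`intercept=True`)
exists. The energy coefficient β₃ multiplies total energy into a naive
peak estimate; it is retained deliberately as the inadequate baseline —
for wire heating it badly mispredicts short high-power sequences, which
motivates the (α, τ) model.

## Sequence book-keeping

- **Duty cycle**: a train of n pulses of duration d with inter-pulse gap
  g occupies n·d + (n−1)·g of each TR — n−1 gaps, because the train ends
  on a pulse. The default 242 × (1 ms + 2 ms) in a 1 s TR gives 72.4 %,
  printing as 72 %. The module must fit in the TR alongside
  n_slices × 62 ms of imaging, else a timing-overflow error.
- **Energy scaling**: for a fixed pulse shape, energy ∝ FA²; E(fa) =
  E_ref·(fa/fa_ref)², rounded to the nearest joule for table output.
  Measured tables carry ±1 J rounding jitter, so agreement is specified
  as within ±1 J per row, not exact.
- **B₁⁺rms combination**: imaging baseline and FA-proportional heating
  contributions add in power, so the combined value is the
  root-sum-square √(B_base² + (fa/fa_ref)²·(B_ref² − B_base²)). This
  models the scanner's reported number; measured values deviate by up to
  ≈ 0.15 μT.
- **Effective power**: E/duration, with the exact inverse provided.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
at the method's published operating point:

- Spatial hotspot: isotropic Gaussian, default σ = 1.5 mm
  (FWHM 3.5 mm, the middle of the observed 2.4–5.6 mm range), on a
  48×48 grid of 0.8 mm pixels; the center pixel follows the log heating
  model exactly.
- Phase encoding: baseline phase is a smooth low-order 2-D polynomial
  with amplitude ≤ 0.4π (exercises wrap-free reference subtraction),
  plus the PRFS term, plus an optional uniform drift (rad/dynamic).
- Noise: complex Gaussian on both quadratures, default 0.0441 of the
  magnitude. At high SNR the phase noise std equals this fraction;
  since the averaged-reference noise is a static per-pixel offset that
  drops out of the temporal std, the unfiltered σ_T is
  0.0441/0.0679 ≈ 0.65 °C — the method's measured unfiltered precision
  — and filtering leaves ≈ 0.21 °C.
- Probe channel: the truth trajectory at the probe pixel, linearly
  interpolated to the probe rate, plus Gaussian noise; no filter lag.
- Calibration datasets: per-power curves from truth α(P), τ(P)
  polynomials plus temperature-domain noise derived from the complex
  noise fraction; zero-power entries give the flat no-heating control.

All generators are pure functions of their seed. Not modelled (hence
not demonstrated by passing tests): EPI ghosting, susceptibility
distortion and signal dropout next to the wire, motion, perfusion, and
fat signal — real acquisitions near implants degrade in ways the
synthetic data does not capture.

## Problem sizes and numerical choices

The simulated studies use 120 dynamics at 1 Hz with heating over
dynamics 10–90 and a 48×48 single-slice grid — the calibration
experiment's own geometry. The filter-precision study uses 10⁴
independent 120-sample series (temporal std after a 10-sample warm-up);
the validation-RMSE study uses 100 seeds with a truth peaking at
11.5 °C (τ = 10 s, αP₀ chosen from the closed-form peak) and reports
the 95th percentile. Monte-Carlo recovery studies use 200–500
replicates. Quantiles use linear interpolation; standard deviations use
ddof = 1; all floating comparisons in tests carry explicit tolerances.

## Known limitations

- The drift model is a per-slice spatial polynomial with causal temporal
  smoothing; spatially structured drift above the chosen order is not
  removed.
- The piecewise-log law assumes a Gaussian source at constant power;
  sequences with strongly time-varying power are summarised by their
  average power only.
- Calibration polynomials are empirical: predictions outside the
  calibrated power range are extrapolations and flagged as such.
- PRFS thermometry itself is invalid in fat and degrades near strong
  susceptibility gradients; the package processes whatever phase it is
  given.
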