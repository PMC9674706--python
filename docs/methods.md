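# Methods

## Model and assumptions

The receptor is a two-state bimolecular binder following the law of mass
action, dy/dt = −k_off·y + k_on·(1 − y)·T(t), with fraction bound y ∈ [0, 1]
and solution concentration T(t) in molar. Two standing assumptions are built
into every simulation:

- **Excess target.** Binding does not deplete T(t); the waveform is an
  exogenous input. This is realistic for surface sensors in flowing samples
  and is not configurable.
- **No mass-transport limitation.** T(t) at the receptor equals the bulk
  concentration; diffusion/advection delays are out of scope.

Detector noise is additive white Gaussian on the *sampled* fraction-bound
signal, specified either as a per-sample standard deviation σ or a two-sided
power spectral density N₀/2 with σ² = f_S·N₀/2. Correlated noise, drift and
non-specific-binding offsets are not modelled (drift-like errors affect the
pre-equilibrium and equilibrium estimators equally and are flagged, not
corrected, by the normalisation code).

## Estimator discretisation

The discrete TEA uses a backward first difference, w′[n] = (w[n] − w[n−1])·f_S.
This is a deliberate, load-bearing choice: the harmonic-balance gain of this
discretisation is

    D₁/C₁ = K_D/(1 − C₀) · (1 + f_S/k_off · (1 − e^(−i·2π·f_T/f_S))),

and every closed-form design quantity (S_N, the SNR relation, K_D*) is the
band integral of that expression. A central difference would change all of
the design equations and is not offered. E[0] is undefined — the estimate
series starts at sample 1 rather than inventing a one-sided start-up rule.

Guard policy: before division, w is clipped to [0, 0.999] and clipped samples
are flagged on the output (`EstimateSeries.clipped`). Negative estimates from
noisy derivatives are reported as-is by default so RMS error statistics are
unbiased; `clamp_negative=True` exists for display. The inverse of the
isotherm clamps y < 0 to zero with a logged warning (noisy traces
legitimately dip below zero); `strict=True` raises instead.

## Frequency-response conventions

The small-signal receptor gain is exposed in two variants that share the same
normalised low-pass factor 1/(1 + iω/Ω_C): the `"printed"` prefactor
k_on/(k_off + k_on·T₀), and a `"linearized"` prefactor carrying an extra
(1 − C₀) from the exact linearisation of the mass-action equation about C₀.
They coincide at low thermodynamic operating point (T₀ ≪ K_D) and diverge as
the sensor saturates. All measurement routines and tests use *normalised*
magnitudes (measured amplitude divided by the equilibrium-predicted
amplitude), where the prefactor cancels, so nothing downstream depends on the
choice.

Phase is reported as the lag of y behind T in positive degrees. Amplitude and
phase are measured by least-squares fitting a single-frequency sinusoid after
discarding a transient of 10/Ω_C (the response settles as e^(−Ω_C·t); ten
time constants leave a relative transient under 5e-5). Corner frequencies are
located by sweeping the drive frequency on a log grid around the analytic
value and interpolating the 1/√2 crossing in log-log coordinates.

## Numerical choices

- **ODE integration.** Piecewise-constant waveforms (step trains, constants)
  use the exact per-segment exponential y → y_eq + (y₀ − y_eq)·e^(−k_eq·Δt).
  Everything else goes through LSODA at rtol 1e-8 / atol 1e-12 with the step
  size capped at 1/500 of the integration span — an adaptive stepper started
  exactly at a fixed point will otherwise grow its step and jump over a
  localized feature such as a concentration spike.
- **Low-pass filter.** Linear-phase Kaiser-window FIR (50 dB design ripple,
  transition band 0.8–1.25× the cutoff, taps normalised for exact unit DC
  gain), applied by symmetric convolution with edge-replicated padding, so
  there is no group delay and constant inputs pass through exactly. The
  half-filter warm-up region at each end is recorded on the trace and
  excluded from all error metrics.
- **SNR convention.** SNR = T₁²/rms_error² (and its inverse for noise
  budgets). The amplitude-squared convention, rather than the sinusoid
  variance T₁²/2, is adopted because it is the one consistent with the
  worked 50 pM / 10 pM RMS ↔ ~14 dB design chain; a variance-based figure is
  trivially 3 dB lower.
- **Affinity optimisation.** S_N is minimised over k_off by log-grid
  bracketing (60 points/decade over 1e-8–1e2 s⁻¹) followed by bounded scalar
  refinement. Derivative root-finding is avoided because the minimum is often
  extremely shallow; results carry a `shallow` flag when S_N stays within 1%
  of the minimum over more than a 2× K_D range, and reported optima should be
  read at 1–2 significant figures in that regime.
- **K_D\* constant.** The shortcut form uses the constant 1.90 (α = 1.90²·f_T);
  the exact asymptote-intersection α² = 2f_S² − f_S³/(π·f_T)·sin(2π·f_T/f_S)
  is available via `exact=True` and agrees with the shortcut within 1% once
  f_S ≥ 10·f_T.
- **Monte-Carlo noise constant.** The empirical TEA output variance is
  proportional to N₀/2·S_N across receptor sweeps (log-log R² > 0.99 in the
  tests), with a proportionality constant near 2. Integrating the squared
  estimator gain over the two-sided band [−f_T, f_T] gives exactly twice the
  S_N closed form, so the constant is a one-sided/two-sided PSD convention
  factor (slightly below 2 in practice because the FIR transition band is not
  ideal). Tests assert the shape agreement and record the constant; they do
  not assume it is 1.

## Synthetic data

The waveform generators define the study conditions used throughout the test
suite: a 50–150 pM trapezoid with a 600 s period (f_T = 4/600 Hz to resolve
four harmonics, f_S = 10·f_T), sinusoids with T₁ ≤ T₀, and a smooth
raised-cosine concentration spike. The spike's published shape is not
specified anywhere, so its functional form here (C¹ raised cosine, baseline
100 pM, peak 500 pM, width 1800 s) is this package's own choice, with defaults
fixed so the mean over the (0, 3600) s analysis window is exactly 200 pM — the
T₀ fed to the K_D* rule of thumb. Spike-based tests therefore assert orderings
and ratios (TEA error < inverse-Langmuir error; SNR peaking near K_D*), never
exact error values.

Sensorgram fixtures emulate a step-schedule binding instrument: exact
exponential binding curves mapped to instrument units through an RMax scale
and baseline offset plus seeded white noise, with the association panel at
80/60/40/30/20 nM and kinetics of a characterised anti-TNFα antibody
(k_on = 3.80e5 M⁻¹s⁻¹, k_off = 2.5e-3 s⁻¹). What the fixtures do *not*
emulate — instrument drift, non-specific binding plateaus, mass-transport
artifacts, vendor global-fit RMax estimation — bounds what passing tests
show: parameter recovery works on clean single-exponential data; performance
on real exported instrument data is untested here.

All stochastic generators require a seed and are bit-reproducible; problem
sizes in the tests (e.g. 200 Monte-Carlo replicates of 2048-sample traces,
7-point k_off sweeps, 10-seed recovery panels) were chosen as the smallest
sizes at which the asserted statistics are stable across seeds.

## Known limitations

- Two-state binding only; three-state receptors (e.g. structure-switching
  aptamers) are not representable.
- Kinetic constants are always *inputs* to the estimator; joint estimation of
  kinetics and concentration is out of scope (use `sensorgram_io.fit_step_kinetics`
  on calibration data first).
- The TEA's accuracy degrades as w → 1; the saturation guard keeps the
  estimate finite but biased near full occupancy. Sensors should be designed
  to operate away from saturation (the optimal K_D is typically above T₀,
  which helps).
- The k_off → ∞ asymptote of S_N as printed, (k_off/k_on)²·f_T, neglects T₀
  relative to K_D; comparisons against it in the tests use T₀ ≪ K_D.
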