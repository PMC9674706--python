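# preqsense

Pre-equilibrium biosensing toolkit: simulate receptor–ligand binding to
arbitrary concentration waveforms, reconstruct the concentration *before* the
receptor equilibrates, and compute the frequency-domain design equations that
tell a sensor designer which receptor kinetics and detector noise levels make
continuous molecular tracking feasible.

## The problem

Continuous biosensors that read target concentration through the equilibrium
binding curve (the Langmuir isotherm, y = T/(K_D + T)) are stuck with a
thermodynamics–kinetics trade-off: sensitive detection of a low-abundance
analyte such as insulin needs a low K_D, and since K_D = k_off/k_on with k_on
capped near 10^6–10^8 M⁻¹s⁻¹, low K_D means slow k_off and slow equilibration.
A small-signal analysis of the mass-action equation

    dy/dt = −k_off·y + k_on·(1 − y)·T(t)

shows the receptor behaves as a first-order low-pass filter with corner
frequency Ω_C = k_off·(1 + T₀/K_D): concentration changes faster than Ω_C are
attenuated, so an equilibrium readout misses them entirely.

The pre-equilibrium alternative is to invert the mass-action equation itself —
the **target estimation algorithm (TEA)**:

    E[n] = (w′[n] + k_off·w[n]) / (k_on·(1 − w[n])),

with w[n] the sampled (noisy) fraction-bound signal and w′[n] its backward
difference. Noise-free, this recovers T(t) instantly for *any* receptor
kinetics. With white detector noise of two-sided power spectral density N₀/2,
the compensation the TEA applies amplifies the noise, and the output noise
power is N₀/2 · S_N(f_T, f_S), where the closed-form noise-scaling function
S_N depends on the receptor's k_off, the mean concentration T₀, the signal
bandwidth f_T and the sampling rate f_S. S_N has a minimum in k_off — there is
an optimal receptor affinity for each sensing task, approximated by the rule
of thumb K_D* ≈ 1.90·√(f_T·T₀/k_on).

## What's in the package

| module | contents |
|---|---|
| `preqsense.binding_kinetics` | Langmuir isotherm and inverse, mass-action ODE simulator (exact exponentials for step inputs), receptor frequency response, corner-frequency measurement |
| `preqsense.waveforms` | sinusoid/trapezoid/spike/step-train test signals, Fourier truncation, synthetic sensorgram fixtures |
| `preqsense.tea` | continuous and discrete TEA, inverse-Langmuir baseline, harmonic-balance gain of the estimator |
| `preqsense.sensor_pipeline` | sample → add noise → zero-phase low-pass → estimate → score; Monte-Carlo output-noise measurement |
| `preqsense.noise_design` | S_N, SNR, optimal-K_D search, K_D* rule of thumb, detector noise budgets, design sweeps |
| `preqsense.sensorgram_io` | instrument CSV I/O, RMax/baseline normalisation, downsampling, k_obs = k_on·[T] + k_off kinetic fitting |

A `preqsense` console script exposes `estimate`, `simulate`, `design`,
`budget` and `fit` subcommands.

## Worked example: designing a continuous insulin sensor

Track insulin fluctuating 50–150 pM with a 10-minute period, resolving four
harmonics (f_T = 4/600 Hz), sampled at f_S = 1/15 Hz:

```python
from preqsense import (ReceptorKinetics, NoiseSpec, make_trapezoid,
                       noise_budget, optimize_kd, run_pipeline)

# 1. Which affinity should the antibody have?
opt = optimize_kd(k_on=1e6, t_0=100e-12, f_t=4/600, f_s=1/15)
print(f"optimal K_D = {opt.kd_opt*1e9:.2f} nM, S_N = {opt.s_n_min:.2e}")
# optimal K_D = 2.86 nM, S_N = 4.33e-18

# 2. How quiet must the detector be for ~14 dB output SNR?
psd_max, sigma_max = noise_budget(13.98, t_1=50e-12, s_n=opt.s_n_min, f_s=1/15)
print(f"sigma <= {sigma_max:.4f} fraction bound")
# sigma <= 0.0012 fraction bound

# 3. Verify with the full nonlinear, noisy pipeline.
wf = make_trapezoid(50e-12, 150e-12, period=600.0)
res = run_pipeline(ReceptorKinetics(1e6, opt.koff_opt), wf, f_s=1/15,
                   noise=NoiseSpec(sigma=0.0012, seed=1), cutoff=4/600)
print(f"TEA: {res.rms_error*1e12:.1f} pM RMS ({res.snr_db:.1f} dB); "
      f"inverse-Langmuir: {res.rms_error_baseline*1e12:.1f} pM RMS")
# TEA: 10.4 pM RMS (13.6 dB); inverse-Langmuir: 39.0 pM RMS
```

The closed-form budget and the Monte-Carlo pipeline agree: with the optimal
receptor and the budgeted detector noise, the estimate error is ~10 pM RMS
(≈14 dB SNR for a 50 pM signal), while the conventional inverse-Langmuir
readout — limited by the receptor's 2.9 mHz corner frequency — is four times
worse regardless of detector quality.

## Further reading

`docs/methods.md` documents the model assumptions, the estimator
discretisation, numerical choices (integrator tolerances, filter design,
guard policies) and the limits of what the synthetic-data tests demonstrate.
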