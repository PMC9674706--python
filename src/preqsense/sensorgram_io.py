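"""Instrument-data bridge: sensorgram CSV I/O, normalisation, downsampling and
step-response kinetic fitting.

A sensorgram is a binding time trace in raw instrument units (for biolayer
interferometry, nm of spectral shift).  Converting it to fraction bound needs
a scale (RMax, the shift at full receptor occupancy) and a baseline offset:
y = (signal - baseline) / RMax.  Kinetic constants come from a standard
step-response analysis: each association segment at analyte concentration [T]
fits a single exponential with observed rate k_obs = k_on*[T] + k_off, so
k_on is the slope of k_obs against concentration, and k_off is averaged over
the dissociation fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import curve_fit
from scipy.stats import linregress

from ._containers import SampledTrace, read_timeseries_csv, write_timeseries_csv
from .sensor_pipeline import _design_taps

__all__ = [
    "RawSensorgram",
    "NormalizedSensorgram",
    "KineticsFitResult",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "normalize",
    "downsample",
    "fit_step_kinetics",
]

#: Bounds on fitted exponential rates, 1/s (guards against runaway fits).
RATE_BOUNDS = (1e-6, 1.0)
#: Dissociation offsets above this fraction of the plateau get flagged as
#: possible non-specific binding (which this module does not correct).
NONSPECIFIC_FLAG_FRACTION = 0.05


@dataclass(frozen=True)
class RawSensorgram:
    """Instrument-unit binding trace with an optional exposure schedule.

    ``schedule`` entries are dicts with keys start_s, end_s, concentration_M.
    """

    t: np.ndarray
    signal: np.ndarray
    schedule: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise ValueError("t and signal must be equal-length 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "signal", s)
        object.__setattr__(self, "schedule", tuple(self.schedule))


@dataclass(frozen=True)
class NormalizedSensorgram:
    """Fraction-bound trace from a normalised sensorgram.

    Real data can overshoot [0, 1] through noise or non-specific binding;
    out-of-range samples are flagged, never clipped.
    """

    t: np.ndarray
    y: np.ndarray
    out_of_range: np.ndarray

    @property
    def native_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


def read_sensorgram_csv(path, schedule_path=None) -> RawSensorgram:
    """Read a two-column (time_s, signal) CSV, optionally with a YAML schedule."""
    t, signal = read_timeseries_csv(path)
    schedule: tuple = ()
    if schedule_path is not None:
        with open(schedule_path) as fh:
            schedule = tuple(yaml.safe_load(fh))
    return RawSensorgram(t=t, signal=signal, schedule=schedule)


def write_sensorgram_csv(path, sensorgram: RawSensorgram) -> None:
    write_timeseries_csv(path, sensorgram.t, sensorgram.signal, value_name="signal")


def normalize(raw: RawSensorgram, rmax: float, baseline: float) -> NormalizedSensorgram:
    """Convert instrument units to fraction bound: (signal - baseline) / RMax."""
    if not rmax > 0:
        raise ValueError("rmax must be positive")
    y = (raw.signal - baseline) / rmax
    return NormalizedSensorgram(t=raw.t, y=y, out_of_range=(y < 0) | (y > 1))


def downsample(trace: NormalizedSensorgram, target_rate: float) -> SampledTrace:
    """Decimate a uniformly sampled trace to ``target_rate`` (Hz).

    An anti-alias FIR filter is applied first whenever the decimation ratio
    exceeds 2.  The achieved rate (native/k for integer stride k) is recorded
    on the returned trace.
    """
    native = trace.native_rate
    if target_rate > native * (1 + 1e-9):
        raise ValueError("cannot upsample: target rate exceeds the native rate")
    k = max(int(round(native / target_rate)), 1)
    y = trace.y
    if k > 2:
        taps = _design_taps(0.4 * native / k, native)
        if taps.size <= y.size:
            y = np.convolve(y, taps, mode="same")
    return SampledTrace(f_s=native / k, w=y[::k], t0=float(trace.t[0]))


@dataclass(frozen=True)
class KineticsFitResult:
    """Kinetic constants recovered from a concentration panel of sensorgrams."""

    k_on: float
    k_on_stderr: float
    k_off: float
    k_off_stderr: float
    k_obs: dict
    r_squared: float
    rmax: float
    baseline: float
    nonspecific_flagged: bool


def _window(sensorgram: RawSensorgram, start: float, end: float):
    mask = (sensorgram.t >= start) & (sensorgram.t <= end)
    return sensorgram.t[mask], sensorgram.signal[mask]


def _seed_rate(t, resid) -> float:
    """Log-linear regression on the decaying residual as an exponential-rate seed."""
    good = resid > 1e-12 * np.max(np.abs(resid)) if np.max(np.abs(resid)) > 0 else resid > 0
    if good.sum() < 3:
        return 1e-3
    slope = np.polyfit(t[good], np.log(resid[good]), 1)[0]
    return float(np.clip(-slope, *RATE_BOUNDS))


def _fit_association(t, s):
    """Fit s(t) = s0 + A*(1 - exp(-k_obs*(t - t0))); return (k_obs, A, s0)."""
    t0 = t[0]
    s0_guess, a_guess = s[0], s[-1] - s[0]
    k_guess = _seed_rate(t - t0, np.abs((s[-1] - s)))

    def model(tt, k, a, s0):
        return s0 + a * (1.0 - np.exp(-k * (tt - t0)))

    popt, pcov = curve_fit(
        model, t, s, p0=[k_guess, a_guess, s0_guess],
        bounds=([RATE_BOUNDS[0], -np.inf, -np.inf], [RATE_BOUNDS[1], np.inf, np.inf]),
        maxfev=20000,
    )
    return popt, pcov


def _fit_dissociation(t, s):
    """Fit s(t) = c + y0*exp(-k_off*(t - t0)); return (k_off, y0, c), cov."""
    t0 = t[0]
    c_guess = s[-1]
    y0_guess = s[0] - c_guess
    k_guess = _seed_rate(t - t0, np.abs(s - c_guess))

    def model(tt, k, y0, c):
        return c + y0 * np.exp(-k * (tt - t0))

    popt, pcov = curve_fit(
        model, t, s, p0=[k_guess, y0_guess, c_guess],
        bounds=([RATE_BOUNDS[0], -np.inf, -np.inf], [RATE_BOUNDS[1], np.inf, np.inf]),
        maxfev=20000,
    )
    return popt, pcov


def fit_step_kinetics(sensorgrams) -> KineticsFitResult:
    """Recover k_on and k_off from a panel of step-response sensorgrams.

    Parameters
    ----------
    sensorgrams : sequence of (RawSensorgram, concentration M)
        Each sensorgram needs a schedule declaring its association (non-zero
        concentration) and dissociation (zero concentration) windows; at
        least two distinct non-zero concentrations are required for the
        k_obs-vs-concentration slope.

    Notes
    -----
    Per-trace association windows fit a single exponential with observed rate
    k_obs; k_on is the ordinary-least-squares slope of k_obs against
    concentration and k_off the mean of the dissociation-fit rates.  Traces
    whose exponential fit fails to converge are excluded with a warning.
    """
    k_obs: dict[float, float] = {}
    koff_fits: list[float] = []
    koff_vars: list[float] = []
    plateau = []
    baselines = []
    flagged = False

    for sensorgram, conc in sensorgrams:
        if not sensorgram.schedule:
            raise ValueError("each sensorgram needs a declared exposure schedule")
        assoc = next((seg for seg in sensorgram.schedule if seg["concentration_M"] > 0), None)
        dissoc = next((seg for seg in sensorgram.schedule if seg["concentration_M"] == 0
                       and (assoc is None or seg["start_s"] >= assoc["end_s"])), None)
        if assoc is not None and conc > 0:
            t, s = _window(sensorgram, assoc["start_s"], assoc["end_s"])
            try:
                (k, a, s0), _ = _fit_association(t, s)
            except RuntimeError:
                warnings.warn(f"association fit failed at {conc:.3g} M; trace excluded")
            else:
                k_obs[float(conc)] = float(k)
                plateau.append((float(s0 + a), float(conc)))
                baselines.append(float(s0))
        if dissoc is not None:
            t, s = _window(sensorgram, dissoc["start_s"], dissoc["end_s"])
            if t.size >= 5 and np.ptp(s) > 0:
                try:
                    (k, y0, c), pcov = _fit_dissociation(t, s)
                except RuntimeError:
                    warnings.warn("dissociation fit failed; trace excluded")
                else:
                    koff_fits.append(float(k))
                    koff_vars.append(float(pcov[0, 0]))
                    if abs(c) > NONSPECIFIC_FLAG_FRACTION * max(abs(y0 + c), 1e-30):
                        flagged = True

    if len(k_obs) < 2:
        raise ValueError("need at least two distinct non-zero concentrations for the k_on slope")
    concs = np.array(sorted(k_obs))
    rates = np.array([k_obs[c] for c in concs])
    line = linregress(concs, rates)

    if not koff_fits:
        raise ValueError("no dissociation segment could be fitted")
    k_off = float(np.mean(koff_fits))
    if len(koff_fits) > 1:
        k_off_se = float(np.std(koff_fits, ddof=1) / np.sqrt(len(koff_fits)))
    else:
        k_off_se = float(np.sqrt(koff_vars[0]))

    # scale/offset estimates from the highest-concentration plateau
    baseline = float(np.mean(baselines)) if baselines else 0.0
    rmax = float("nan")
    if plateau and line.slope > 0:
        sig, conc = max(plateau, key=lambda p: p[1])
        kd = k_off / line.slope
        y_eq = conc / (kd + conc)
        if y_eq > 0:
            rmax = (sig - baseline) / y_eq

    return KineticsFitResult(
        k_on=float(line.slope), k_on_stderr=float(line.stderr),
        k_off=k_off, k_off_stderr=k_off_se,
        k_obs={float(c): float(k_obs[c]) for c in concs},
        r_squared=float(line.rvalue**2),
        rmax=rmax, baseline=baseline, nonspecific_flagged=flagged,
    )
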