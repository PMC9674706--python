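"""Target-concentration test signals and synthetic instrument fixtures.

Waveforms are callables T(t) in molar with a little metadata (mean, period,
whether they are piecewise constant, which unlocks the exact-exponential ODE
path).  The Fourier-truncation utility quantifies how much frequency content
a waveform needs — sharp transitions demand more harmonics, which is what
drives the choice of the design bandwidth f_T.  The sensorgram fixture
generator emulates a step-schedule binding instrument (e.g. biolayer
interferometry): fraction bound mapped to instrument units through an RMax
scale and baseline offset, plus seeded white detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from ._containers import DomainError, write_timeseries_csv
from .binding_kinetics import ReceptorKinetics, simulate_binding

__all__ = [
    "ConcentrationWaveform",
    "Sinusoid",
    "Trapezoid",
    "RaisedCosineSpike",
    "StepTrain",
    "Constant",
    "FourierWaveform",
    "SensorgramFixture",
    "make_sinusoid",
    "make_trapezoid",
    "make_spike",
    "make_step_train",
    "fourier_truncate",
    "make_sensorgram_fixture",
]


class ConcentrationWaveform:
    """Continuous-time target concentration T(t), molar.

    Subclasses implement ``_evaluate``; instances are called on scalar or
    array time arguments.  ``period`` is None for aperiodic waveforms.
    """

    kind: str = "custom"
    period: float | None = None
    is_piecewise_constant: bool = False

    def _evaluate(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self._evaluate(np.atleast_1d(t))
        return float(out[0]) if t.ndim == 0 else out

    def mean_over(self, t0: float, t1: float, n: int = 20001) -> float:
        """Time-averaged concentration over [t0, t1] (trapezoidal quadrature)."""
        t = np.linspace(t0, t1, n)
        return float(np.trapezoid(self(t), t))/ (t1 - t0)

    @property
    def mean(self) -> float:
        """Mean over one period (periodic) or the declared analysis window."""
        if self.period is not None:
            return self.mean_over(0.0, self.period)
        raise ValueError("aperiodic waveform: use mean_over(t0, t1)")

    def to_csv(self, path, t) -> None:
        write_timeseries_csv(path, t, self(np.asarray(t, float)), value_name="concentration_M")

    def params(self) -> dict:
        return {"kind": self.kind}

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.params(), fh)


@dataclass
class Sinusoid(ConcentrationWaveform):
    """T(t) = T_1 * cos(2*pi*f_T*t) + T_0."""

    t_0: float
    t_1: float
    f_t: float
    kind: str = field(default="sinusoid", init=False)

    def __post_init__(self) -> None:
        if self.t_1 < 0 or self.t_0 < 0:
            raise DomainError("concentrations must be non-negative")
        if self.t_1 > self.t_0:
            raise DomainError("T_1 > T_0 would make the concentration negative")
        if not self.f_t > 0:
            raise ValueError("f_T must be positive")
        self.period = 1.0 / self.f_t

    def _evaluate(self, t):
        return self.t_1 * np.cos(2 * np.pi * self.f_t * t) + self.t_0

    @property
    def mean(self) -> float:
        return self.t_0

    def params(self):
        return {"kind": self.kind, "t_0": self.t_0, "t_1": self.t_1, "f_t": self.f_t}


@dataclass
class Trapezoid(ConcentrationWaveform):
    """Periodic trapezoid: low -> ramp up -> high plateau -> ramp down -> low.

    Segment fractions of the period: rise_frac up, high_frac at ``high``,
    rise_frac down, remainder at ``low``.  The published test signal shape is
    shown but not parameterised; equal ramp and plateau quarters are the
    default here and are configurable.
    """

    low: float
    high: float
    period: float
    rise_frac: float = 0.25
    high_frac: float = 0.25
    kind: str = field(default="trapezoid", init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high:
            raise DomainError("need 0 <= low < high")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not (0 < self.rise_frac < 1 and 0 < self.high_frac < 1
                and 2 * self.rise_frac + self.high_frac <= 1):
            raise ValueError("need 2*rise_frac + high_frac <= 1 with fractions in (0, 1)")

    def _evaluate(self, t):
        phase = np.mod(t, self.period) / self.period
        r, h = self.rise_frac, self.high_frac
        out = np.full(phase.shape, self.low, dtype=float)
        up = phase < r
        out[up] = self.low + (self.high - self.low) * phase[up] / r
        flat = (phase >= r) & (phase < r + h)
        out[flat] = self.high
        down = (phase >= r + h) & (phase < 2 * r + h)
        out[down] = self.high - (self.high - self.low) * (phase[down] - r - h) / r
        return out

    @property
    def mean(self) -> float:
        # closed form: plateau + two half ramps
        return self.low + (self.high - self.low) * (self.high_frac + self.rise_frac)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.high - self.low)

    def params(self):
        return {"kind": self.kind, "low": self.low, "high": self.high,
                "period": self.period, "rise_frac": self.rise_frac,
                "high_frac": self.high_frac}


@dataclass
class RaisedCosineSpike(ConcentrationWaveform):
    """Smooth aperiodic pulse: baseline + (peak-baseline)/2 * (1 + cos) inside
    a window of ``width`` seconds centred on ``center``; baseline elsewhere.

    Continuously differentiable (C^1).  The defaults produce a mean of 200 pM
    over the default (0, 3600) s analysis window, a concentration spike on the
    scale of a post-meal insulin excursion.
    """

    baseline: float = 1e-10
    peak: float = 5e-10
    center: float = 1800.0
    width: float = 1800.0
    analysis_window: tuple[float, float] = (0.0, 3600.0)
    kind: str = field(default="spike", init=False)

    def __post_init__(self) -> None:
        if not self.peak > self.baseline >= 0:
            raise DomainError("need peak > baseline >= 0")
        if not self.width > 0:
            raise ValueError("width must be positive")

    def _evaluate(self, t):
        x = (t - self.center) / self.width
        out = np.full(t.shape, self.baseline, dtype=float)
        inside = np.abs(x) < 0.5
        out[inside] = self.baseline + (self.peak - self.baseline) * 0.5 * (
            1.0 + np.cos(2 * np.pi * x[inside])
        )
        return out

    @property
    def effective_mean(self) -> float:
        """Mean over the analysis window, the T_0 fed to the K_D* rule of thumb.

        Closed form when the pulse lies inside the window:
        baseline + (peak - baseline) * width / (2 * window_length).
        """
        t0, t1 = self.analysis_window
        lo, hi = self.center - self.width / 2, self.center + self.width / 2
        if t0 <= lo and hi <= t1:
            return self.baseline + (self.peak - self.baseline) * self.width / (2 * (t1 - t0))
        return self.mean_over(t0, t1)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.peak - self.baseline)

    def params(self):
        return {"kind": self.kind, "baseline": self.baseline, "peak": self.peak,
                "center": self.center, "width": self.width,
                "analysis_window": list(self.analysis_window)}


@dataclass
class StepTrain(ConcentrationWaveform):
    """Piecewise-constant schedule of (concentration, duration) steps.

    Holds the final concentration beyond the schedule.  Unlocks the exact
    exponential integration path.
    """

    steps: tuple
    t_start: float = 0.0
    kind: str = field(default="step_train", init=False)
    is_piecewise_constant: bool = True

    def __post_init__(self) -> None:
        steps = tuple((float(c), float(d)) for c, d in self.steps)
        if not steps:
            raise ValueError("need at least one step")
        for c, d in steps:
            if c < 0:
                raise DomainError("step concentrations must be non-negative")
            if d <= 0:
                raise ValueError("step durations must be positive")
        self.steps = steps

    def _edges(self) -> np.ndarray:
        return self.t_start + np.concatenate([[0.0], np.cumsum([d for _, d in self.steps])])

    def breakpoints(self, t0: float, t1: float) -> np.ndarray:
        e = self._edges()[1:-1]
        return e[(e > t0) & (e < t1)]

    def _evaluate(self, t):
        edges = self._edges()
        concs = np.array([c for c, _ in self.steps])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(concs) - 1)
        return concs[idx]

    def params(self):
        return {"kind": self.kind, "steps": [list(s) for s in self.steps],
                "t_start": self.t_start}


@dataclass
class Constant(ConcentrationWaveform):
    """Fixed concentration; trivially piecewise constant."""

    value: float
    kind: str = field(default="constant", init=False)
    is_piecewise_constant: bool = True

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError("concentration must be non-negative")

    def breakpoints(self, t0, t1):
        return np.empty(0)

    def _evaluate(self, t):
        return np.full(t.shape, self.value, dtype=float)

    @property
    def mean(self) -> float:
        return self.value

    def params(self):
        return {"kind": self.kind, "value": self.value}


@dataclass
class FourierWaveform(ConcentrationWaveform):
    """Truncated Fourier series a_0 + sum_k a_k cos + b_k sin over a period."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    period: float
    kind: str = field(default="fourier", init=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("cosine/sine coefficient length mismatch")

    @property
    def n_harmonics(self) -> int:
        return self.a.size

    def _evaluate(self, t):
        out = np.full(t.shape, self.a0, dtype=float)
        w0 = 2 * np.pi / self.period
        for k in range(1, self.n_harmonics + 1):
            out += self.a[k - 1] * np.cos(k * w0 * t) + self.b[k - 1] * np.sin(k * w0 * t)
        return out

    @property
    def mean(self) -> float:
        return self.a0

    def params(self):
        return {"kind": self.kind, "a0": self.a0, "a": self.a.tolist(),
                "b": self.b.tolist(), "period": self.period}


def make_sinusoid(t_0: float, t_1: float, f_t: float) -> Sinusoid:
    """Sinusoidal test signal with mean T_0, amplitude T_1 and frequency f_T (Hz)."""
    return Sinusoid(t_0=t_0, t_1=t_1, f_t=f_t)


def make_trapezoid(low: float, high: float, period: float,
                   rise_frac: float = 0.25, high_frac: float = 0.25) -> Trapezoid:
    return Trapezoid(low=low, high=high, period=period,
                     rise_frac=rise_frac, high_frac=high_frac)


def make_spike(baseline: float = 1e-10, peak: float = 5e-10,
               center: float = 1800.0, width: float = 1800.0,
               analysis_window: tuple[float, float] = (0.0, 3600.0)) -> RaisedCosineSpike:
    return RaisedCosineSpike(baseline=baseline, peak=peak, center=center,
                             width=width, analysis_window=analysis_window)


def make_step_train(steps, t_start: float = 0.0) -> StepTrain:
    return StepTrain(steps=tuple(steps), t_start=t_start)


def fourier_truncate(waveform: ConcentrationWaveform, n_harmonics: int,
                     period: float | None = None, n_grid: int = 4097) -> FourierWaveform:
    """Fourier series of a periodic waveform truncated at ``n_harmonics``.

    Coefficients come from a DFT of one period sampled on ``n_grid`` points,
    so with n_harmonics up to (n_grid - 1) // 2 (odd n_grid) the truncation
    reproduces the grid samples to machine precision.
    """
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be non-negative")
    period = period if period is not None else waveform.period
    if period is None:
        raise ValueError("waveform is aperiodic and no period was given")
    if n_harmonics > (n_grid - 1) // 2:
        raise ValueError("n_harmonics exceeds the Nyquist limit of the coefficient grid")
    t = np.arange(n_grid) * (period / n_grid)
    samples = np.asarray(waveform(t), dtype=float)
    spec = np.fft.rfft(samples)
    a0 = float(spec[0].real) / n_grid
    k = np.arange(1, n_harmonics + 1)
    a = 2.0 * spec[k].real / n_grid
    b = -2.0 * spec[k].imag / n_grid
    return FourierWaveform(a0=a0, a=a, b=b, period=period)


@dataclass(frozen=True)
class SensorgramFixture:
    """Synthetic step-schedule sensorgram with retained ground truth.

    raw_signal = baseline + rmax * y_true + N(0, noise_sigma^2) exactly by
    construction; the noise stream is fully determined by ``seed``.
    """

    t: np.ndarray
    raw_signal: np.ndarray
    y_true: np.ndarray
    true_kinetics: ReceptorKinetics
    rmax: float
    baseline: float
    noise_sigma: float
    seed: int
    schedule: tuple

    def schedule_dicts(self) -> list[dict]:
        out, start = [], float(self.t[0])
        for conc, dur in self.schedule:
            out.append({"start_s": start, "end_s": start + dur, "concentration_M": conc})
            start += dur
        return out

    def to_csv(self, path) -> None:
        write_timeseries_csv(path, self.t, self.raw_signal, value_name="signal")

    def write_sidecar(self, path) -> None:
        meta = {
            "k_on": self.true_kinetics.k_on, "k_off": self.true_kinetics.k_off,
            "rmax": self.rmax, "baseline": self.baseline,
            "noise_sigma": self.noise_sigma, "seed": self.seed,
            "schedule": self.schedule_dicts(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(meta, fh)


def make_sensorgram_fixture(
    kin: ReceptorKinetics,
    steps,
    rmax: float = 1.0,
    baseline: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_rate: float = 1.0,
    y0: float = 0.0,
) -> SensorgramFixture:
    """Simulate a step-concentration binding experiment in instrument units.

    Parameters
    ----------
    steps : sequence of (concentration M, duration s)
        Analyte exposure schedule, e.g. ``[(20e-9, 300), (0.0, 300)]``.
    rmax : float
        Instrument units per unit fraction bound.
    noise_sigma : float
        Additive white Gaussian noise, instrument units; 0 for a noiseless
        ground-truth fixture.
    """
    if not sample_rate > 0:
        raise ValueError("sample_rate must be positive")
    wf = make_step_train(steps)
    total = sum(d for _, d in wf.steps)
    t = np.arange(0.0, total + 0.5 / sample_rate, 1.0 / sample_rate)
    series = simulate_binding(kin, wf, y0, t)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=t.size) if noise_sigma > 0 else np.zeros(t.size)
    raw = baseline + rmax * series.y + noise
    return SensorgramFixture(
        t=t, raw_signal=raw, y_true=series.y, true_kinetics=kin,
        rmax=rmax, baseline=baseline, noise_sigma=noise_sigma, seed=seed,
        schedule=wf.steps,
    )
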