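"""Equilibrium and dynamic models of a bimolecular receptor.

A surface-immobilised receptor binding a solution-phase target T follows the
law of mass action

    dy/dt = -k_off * y + k_on * (1 - y) * T(t),

where y is the fraction of receptors bound.  At equilibrium this reduces to
the Langmuir isotherm y = T / (K_D + T) with K_D = k_off / k_on.  For a small
sinusoidal concentration oscillation about a mean T_0, the receptor behaves
as a first-order low-pass filter with corner frequency

    Omega_C = k_off + k_on * T_0 = k_off * (1 + T_0 / K_D),

so the ratio T_0 / K_D (the thermodynamic operating point, TOP) sets how far
above k_off the receptor can still track concentration changes.  This module
provides the isotherm and its inverse, an ODE simulator for arbitrary
concentration waveforms (with an exact exponential fast path for
piecewise-constant inputs), the analytic frequency response, and measurement
routines that extract amplitude, phase and corner frequency from simulated
traces.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._containers import (
    BoundFractionSeries,
    DomainError,
    SaturationError,
    SweepRangeError,
)

__all__ = [
    "ReceptorKinetics",
    "OperatingPoint",
    "FrequencyResponsePoint",
    "BoundFractionSeries",
    "DomainError",
    "SaturationError",
    "langmuir_fraction",
    "inverse_langmuir",
    "corner_frequency",
    "operating_point",
    "receptor_frequency_response",
    "simulate_binding",
    "measure_amplitude_phase",
    "measure_corner_frequency",
]

logger = logging.getLogger(__name__)

#: Relative tolerance used by the adaptive ODE integrator.
ODE_RTOL = 1e-8
#: Absolute tolerance used by the adaptive ODE integrator (fraction bound).
ODE_ATOL = 1e-12
#: Transient discarded before steady-state measurements, in units of 1/Omega_C.
DEFAULT_SETTLE_FACTOR = 10.0


@dataclass(frozen=True)
class ReceptorKinetics:
    """Association/dissociation rate constants of a bimolecular receptor.

    Parameters
    ----------
    k_on : float
        Association rate constant, 1/(M*s).  Typical proteins fall in
        1e6 - 1e7; ~1e8 is a physical upper limit.
    k_off : float
        Dissociation rate constant, 1/s.

    The affinity ``k_d`` is always derived as ``k_off / k_on``.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError("k_on must be positive")
        if self.k_off < 0:
            raise ValueError("k_off must be non-negative")

    @property
    def k_d(self) -> float:
        """Dissociation constant K_D = k_off / k_on, molar."""
        return self.k_off / self.k_on

    @classmethod
    def from_kd(cls, k_on: float, k_d: float) -> "ReceptorKinetics":
        return cls(k_on=k_on, k_off=k_on * k_d)


@dataclass(frozen=True)
class OperatingPoint:
    """Steady-state operating point of a receptor at mean concentration T_0."""

    t_0: float
    c_0: float
    omega_c: float
    top: float


@dataclass(frozen=True)
class FrequencyResponsePoint:
    """Receptor gain at a single angular frequency.

    ``gain`` is the complex amplitude ratio C_1/T_1 (fraction bound per molar);
    ``normalized_gain`` is the unitless low-pass factor 1/(1 + i*omega/Omega_C)
    shared by both prefactor variants.
    """

    omega: float
    gain: complex
    normalized_gain: complex

    @property
    def magnitude(self) -> float:
        return abs(self.gain)

    @property
    def normalized_magnitude(self) -> float:
        return abs(self.normalized_gain)

    @property
    def phase_lag_deg(self) -> float:
        """Phase lag of y behind T, positive degrees."""
        return float(-np.degrees(np.angle(self.normalized_gain)))


def langmuir_fraction(T, kin: ReceptorKinetics):
    """Equilibrium fraction bound y = T / (K_D + T).

    Parameters
    ----------
    T : float or ndarray
        Target concentration, molar, non-negative.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise DomainError("concentration must be non-negative")
    out = T / (kin.k_d + T)
    return float(out) if out.ndim == 0 else out


def inverse_langmuir(y, kin: ReceptorKinetics, *, strict: bool = False):
    """Invert the Langmuir isotherm: T = K_D * y / (1 - y).

    Noisy traces legitimately dip below zero; by default negative inputs are
    clamped to zero (with a logged warning) rather than rejected.  ``strict``
    raises instead.  y >= 1 is always an error: the isotherm saturates.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y >= 1):
        raise SaturationError("fraction bound >= 1: isotherm not invertible")
    if np.any(y < 0):
        if strict:
            raise DomainError("fraction bound must be non-negative")
        logger.warning("inverse_langmuir: clamping %d negative sample(s) to 0", int(np.sum(y < 0)))
        y = np.clip(y, 0.0, None)
    out = kin.k_d * y / (1.0 - y)
    return float(out) if out.ndim == 0 else out


def corner_frequency(kin: ReceptorKinetics, t_0: float) -> float:
    """Corner (pole) frequency Omega_C = k_off + k_on * T_0, rad/s."""
    if t_0 < 0:
        raise DomainError("mean concentration must be non-negative")
    return kin.k_off + kin.k_on * t_0


def operating_point(kin: ReceptorKinetics, t_0: float) -> OperatingPoint:
    """Mean fraction bound, corner frequency and TOP at mean concentration T_0."""
    c_0 = langmuir_fraction(t_0, kin)
    return OperatingPoint(
        t_0=t_0,
        c_0=float(c_0),
        omega_c=corner_frequency(kin, t_0),
        top=t_0 / kin.k_d if kin.k_d > 0 else np.inf,
    )


def receptor_frequency_response(
    kin: ReceptorKinetics,
    t_0: float,
    omega: float,
    variant: str = "printed",
) -> FrequencyResponsePoint:
    """Small-signal gain C_1/T_1 of the receptor at angular frequency omega.

    Two prefactor conventions are exposed; they share the identical
    normalised low-pass factor and differ only in DC scale:

    - ``"printed"``: k_on / (k_off + k_on*T_0) * 1/(1 + i*omega/Omega_C).
    - ``"linearized"``: the printed prefactor multiplied by (1 - C_0), the
      exact small-signal linearisation of the mass-action ODE about C_0.

    The variants coincide as T_0/K_D -> 0 and diverge at high TOP; normalised
    quantities (where the prefactor cancels) are identical for both.
    """
    if omega < 0:
        raise DomainError("omega must be non-negative")
    omega_c = corner_frequency(kin, t_0)
    lp = 1.0 / (1.0 + 1j * omega / omega_c)
    prefactor = kin.k_on / omega_c
    if variant == "linearized":
        prefactor *= 1.0 - langmuir_fraction(t_0, kin)
    elif variant != "printed":
        raise ValueError(f"unknown variant {variant!r}")
    return FrequencyResponsePoint(omega=omega, gain=prefactor * lp, normalized_gain=lp)


def _simulate_piecewise_constant(kin, waveform, y0, t_grid):
    """Exact per-segment exponential solution for piecewise-constant T(t)."""
    breaks = np.asarray(waveform.breakpoints(t_grid[0], t_grid[-1]), dtype=float)
    edges = np.unique(np.concatenate([[t_grid[0]], breaks, [t_grid[-1]]]))
    edges = edges[(edges >= t_grid[0]) & (edges <= t_grid[-1])]
    y = np.empty_like(t_grid)
    y_seg = float(y0)
    for left, right in zip(edges[:-1], edges[1:]):
        T_c = float(waveform(0.5 * (left + right)))
        k_eq = kin.k_on * T_c + kin.k_off
        y_eq = kin.k_on * T_c / k_eq if k_eq > 0 else y_seg
        mask = (t_grid >= left) & (t_grid <= right)
        if k_eq > 0:
            y[mask] = y_eq + (y_seg - y_eq) * np.exp(-k_eq * (t_grid[mask] - left))
            y_seg = y_eq + (y_seg - y_eq) * np.exp(-k_eq * (right - left))
        else:
            y[mask] = y_seg
    return y


def simulate_binding(
    kin: ReceptorKinetics,
    waveform,
    y0: float,
    t_grid,
) -> BoundFractionSeries:
    """Integrate the mass-action ODE for an arbitrary concentration waveform.

    Piecewise-constant waveforms are advanced with the exact per-segment
    exponential y -> y_eq + (y0 - y_eq) * exp(-k_eq * dt), k_eq = k_on*T + k_off;
    everything else goes through an adaptive stiff-capable integrator (LSODA)
    at relative tolerance 1e-8.

    Parameters
    ----------
    waveform : ConcentrationWaveform
        Callable T(t), molar; must be non-negative on the grid.
    y0 : float
        Initial fraction bound, in [0, 1].
    t_grid : ndarray
        Strictly increasing evaluation times, seconds.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    if not 0 <= y0 <= 1:
        raise DomainError("y0 must lie in [0, 1]")
    T_on_grid = np.asarray(waveform(t_grid), dtype=float)
    if np.any(T_on_grid < 0):
        raise DomainError("concentration waveform is negative on the grid")

    if getattr(waveform, "is_piecewise_constant", False):
        y = _simulate_piecewise_constant(kin, waveform, y0, t_grid)
    else:
        def rhs(t, y):
            return -kin.k_off * y + kin.k_on * (1.0 - y) * waveform(t)

        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            [float(y0)],
            t_eval=t_grid,
            method="LSODA",
            rtol=ODE_RTOL,
            atol=ODE_ATOL,
            # cap the step so an adaptive stepper started at a fixed point
            # cannot jump over localized waveform features (e.g. a spike)
            max_step=(t_grid[-1] - t_grid[0]) / 500.0,
        )
        if not sol.success:
            raise RuntimeError(f"binding ODE integration failed: {sol.message}")
        y = sol.y[0]

    if y.min() < -1e-6 or y.max() > 1 + 1e-6:
        raise RuntimeError("integrated fraction bound left [0, 1] beyond solver tolerance")
    return BoundFractionSeries(t=t_grid, y=np.clip(y, 0.0, 1.0))


def measure_amplitude_phase(
    series: BoundFractionSeries,
    f: float,
    settle: float,
) -> tuple[float, float]:
    """Least-squares single-frequency sinusoid fit after discarding a transient.

    Fits y(t) = a*cos(2*pi*f*t) + b*sin(2*pi*f*t) + c on t >= settle and
    returns (amplitude, phase lag in positive degrees).  The window must cover
    at least three periods of f.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    mask = series.t >= settle
    t, y = series.t[mask], series.y[mask]
    if t.size < 8 or (t[-1] - t[0]) < 3.0 / f:
        raise ValueError("post-settle window shorter than three periods")
    omega = 2 * np.pi * f
    design = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.ones_like(t)])
    (a, b, _), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = float(np.hypot(a, b))
    phase_lag = float(np.degrees(np.arctan2(b, a)))
    return amplitude, phase_lag


def _steady_state_amplitude(kin, t_0, t_1, omega, *, settle_factor, n_periods, pts_per_period):
    """Simulated steady-state first-harmonic amplitude and phase at drive omega."""
    # local import: waveforms depends on binding_kinetics for fixtures
    from .waveforms import make_sinusoid

    f = omega / (2 * np.pi)
    omega_c = corner_frequency(kin, t_0)
    settle = settle_factor / omega_c
    t_end = settle + n_periods / f
    # coarse grid through the transient, fine grid over the measurement window
    t_settle = np.linspace(0.0, settle, 64, endpoint=False)
    t_meas = settle + np.arange(n_periods * pts_per_period + 1) / (pts_per_period * f)
    t_grid = np.concatenate([t_settle, t_meas])
    wf = make_sinusoid(t_0, t_1, f)
    series = simulate_binding(kin, wf, float(langmuir_fraction(t_0, kin)), t_grid)
    amp, phase = measure_amplitude_phase(series, f, settle)
    # equilibrium-predicted amplitude: first harmonic of the isotherm applied
    # to the waveform itself (what an infinitely fast receptor would show)
    y_eq = langmuir_fraction(np.maximum(wf(t_meas), 0.0), kin)
    eq_series = BoundFractionSeries(t=t_meas, y=y_eq)
    amp_eq, _ = measure_amplitude_phase(eq_series, f, settle)
    del t_end
    return amp, phase, amp_eq


def measure_normalized_amplitude(
    kin: ReceptorKinetics,
    t_0: float,
    t_1: float,
    omega: float,
    *,
    settle_factor: float = DEFAULT_SETTLE_FACTOR,
    n_periods: int = 4,
    pts_per_period: int = 96,
) -> tuple[float, float]:
    """Simulated amplitude (normalised to the equilibrium response) and phase lag.

    Normalisation divides the measured first-harmonic amplitude by the
    first-harmonic amplitude an equilibrated (infinitely fast) receptor would
    produce for the same waveform, so the prefactor convention cancels.
    """
    amp, phase, amp_eq = _steady_state_amplitude(
        kin, t_0, t_1, omega,
        settle_factor=settle_factor, n_periods=n_periods, pts_per_period=pts_per_period,
    )
    return amp / amp_eq, phase


def measure_corner_frequency(
    kin: ReceptorKinetics,
    t_0: float,
    t_1: float,
    *,
    n_sweep: int = 9,
    span_decades: float = 1.2,
    settle_factor: float = DEFAULT_SETTLE_FACTOR,
    n_periods: int = 4,
    pts_per_period: int = 96,
) -> float:
    """Locate the -3 dB frequency of the simulated receptor, rad/s.

    Sweeps the drive frequency on a log grid spanning ``span_decades`` around
    the analytic corner frequency, measures the normalised amplitude at each
    point, and returns the frequency where it crosses 1/sqrt(2), interpolated
    in log-log coordinates.  For large oscillations (T_1 near T_0 at high TOP)
    the measured value legitimately deviates from the analytic expression.
    """
    if t_1 >= t_0:
        warnings.warn("T_1 >= T_0 leaves the small-signal regime; corner estimate may deviate")
    center = corner_frequency(kin, t_0)
    omegas = center * np.logspace(-span_decades / 2, span_decades / 2, n_sweep)
    amps = np.array([
        measure_normalized_amplitude(
            kin, t_0, t_1, w,
            settle_factor=settle_factor, n_periods=n_periods, pts_per_period=pts_per_period,
        )[0]
        for w in omegas
    ])
    target = 1.0 / np.sqrt(2.0)
    below = amps < target
    if not below.any() or below.all():
        raise SweepRangeError("1/sqrt(2) crossing not bracketed by the frequency sweep")
    i = int(np.argmax(below))  # first point under the threshold
    if i == 0:
        raise SweepRangeError("sweep starts below the -3 dB level")
    la, lb = np.log(amps[i - 1]), np.log(amps[i])
    lw_a, lw_b = np.log(omegas[i - 1]), np.log(omegas[i])
    frac = (np.log(target) - la) / (lb - la)
    return float(np.exp(lw_a + frac * (lw_b - lw_a)))
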