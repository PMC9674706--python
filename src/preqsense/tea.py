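"""Pre-equilibrium target estimation algorithm (TEA) and its design equations.

The TEA inverts the law of mass action instead of the equilibrium isotherm:

    T(t) = (dy/dt + k_off * y) / (k_on * (1 - y))            (continuous)
    E[n] = (w'[n] + k_off * w[n]) / (k_on * (1 - w[n]))      (discrete)

so a receptor with any kinetics can, in the noise-free limit, report the
instantaneous concentration without waiting for equilibration.  The discrete
derivative is a backward first difference, w'[n] = (w[n] - w[n-1]) * f_S —
the discretisation whose frequency response carries the (1 - exp(-i*2*pi*
f_T/f_S)) factor used throughout the design math.  In the frequency domain
the estimator is a discrete-time high-pass filter,

    D_1/C_1 = K_D/(1 - C_0) * (1 + f_S/k_off * (1 - exp(-i*2*pi*f_T/f_S))),

which reduces to the inverse-Langmuir prefactor at f_T = 0 and applies a
compensation factor (1 + 2*f_S/k_off) at the Nyquist frequency — slow
receptors need more compensation, which is what amplifies detector noise.
"""

from __future__ import annotations

import logging

import numpy as np

from dataclasses import dataclass

from ._containers import (
    DomainError,
    EstimateSeries,
    SampledTrace,
    SaturationError,
)
from .binding_kinetics import ReceptorKinetics, inverse_langmuir

__all__ = [
    "EstimateSeries",
    "TeaFrequencyGain",
    "AliasingError",
    "tea_continuous",
    "tea_discrete",
    "inverse_langmuir_series",
    "tea_frequency_gain",
]

logger = logging.getLogger(__name__)

#: Saturation guard: w is clipped to [0, 1 - SATURATION_EPS] before division.
SATURATION_EPS = 1e-3


class AliasingError(ValueError):
    """Requested target frequency above the Nyquist frequency f_S/2."""


@dataclass(frozen=True)
class TeaFrequencyGain:
    """Complex estimator gain D_1/C_1 at one (f_T, f_S) pair, M per fraction bound."""

    f_t: float
    f_s: float
    gain: complex
    d_0: float

    @property
    def magnitude(self) -> float:
        return abs(self.gain)


def tea_continuous(y, dydt, kin: ReceptorKinetics, *, clamp_negative: bool = False):
    """Continuous-time estimate T = (dy/dt + k_off*y) / (k_on*(1 - y)).

    Reduces to the inverse-Langmuir when dy/dt = 0.  Negative estimates can
    arise from noisy derivatives; they are returned as-is unless
    ``clamp_negative``.
    """
    y = np.asarray(y, dtype=float)
    dydt = np.asarray(dydt, dtype=float)
    if np.any(y < 0):
        raise DomainError("fraction bound must be non-negative")
    if np.any(y >= 1):
        raise SaturationError("fraction bound >= 1: estimator is singular")
    out = (dydt + kin.k_off * y) / (kin.k_on * (1.0 - y))
    if clamp_negative:
        out = np.clip(out, 0.0, None)
    return float(out) if out.ndim == 0 else out


def _guard(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clip samples to [0, 1 - eps]; return (clipped values, mask of clipped)."""
    hi = 1.0 - SATURATION_EPS
    mask = (w < 0.0) | (w > hi)
    if mask.any():
        logger.warning("saturation guard clipped %d of %d samples", int(mask.sum()), w.size)
    return np.clip(w, 0.0, hi), mask


def tea_discrete(
    trace: SampledTrace,
    kin: ReceptorKinetics,
    *,
    clamp_negative: bool = False,
) -> EstimateSeries:
    """Apply the discrete TEA to a sampled trace.

    The estimate starts at sample index 1 (the backward difference has no
    value at n = 0).  Samples outside [0, 1 - eps) are clipped and flagged;
    an all-saturated trace is rejected.
    """
    w = trace.w
    if np.all(w >= 1.0 - SATURATION_EPS):
        raise SaturationError("entire trace is saturated")
    wc, mask = _guard(w)
    dw = (wc[1:] - wc[:-1]) * trace.f_s
    e = (dw + kin.k_off * wc[1:]) / (kin.k_on * (1.0 - wc[1:]))
    if clamp_negative:
        e = np.clip(e, 0.0, None)
    return EstimateSeries(t=trace.t[1:], e=e, clipped=(mask[1:] | mask[:-1]))


def inverse_langmuir_series(
    trace: SampledTrace,
    kin: ReceptorKinetics,
    *,
    clamp_negative: bool = False,
) -> EstimateSeries:
    """Element-wise inverse-Langmuir baseline estimator with the same guard.

    Dropped to the same support as :func:`tea_discrete` (samples 1..N-1) so
    the two estimators compare sample-for-sample.
    """
    if np.all(trace.w >= 1.0 - SATURATION_EPS):
        raise SaturationError("entire trace is saturated")
    wc, mask = _guard(trace.w)
    e = inverse_langmuir(wc, kin)
    if clamp_negative:
        e = np.clip(e, 0.0, None)
    return EstimateSeries(t=trace.t[1:], e=np.atleast_1d(e)[1:], clipped=mask[1:])


def tea_frequency_gain(
    kin: ReceptorKinetics,
    c_0: float,
    f_t: float,
    f_s: float,
) -> TeaFrequencyGain:
    """Harmonic-balance gain of the discrete TEA at target frequency f_T.

    Valid for 0 <= f_T <= f_S/2; above Nyquist the target is aliased and an
    error is raised.  Limits: f_T = 0 gives K_D/(1 - C_0) (the inverse-
    Langmuir slope factor); f_T = f_S/2 multiplies that by (1 + 2*f_S/k_off).
    """
    if not 0 <= c_0 < 1:
        raise DomainError("C_0 must lie in [0, 1)")
    if f_t < 0 or f_s <= 0:
        raise ValueError("frequencies must be non-negative (f_S positive)")
    if f_t > f_s / 2 + 1e-15:
        raise AliasingError(f"f_T = {f_t} Hz exceeds the Nyquist frequency {f_s / 2} Hz")
    if kin.k_off <= 0:
        raise DomainError("k_off must be positive: zero off-rate needs infinite compensation")
    prefactor = kin.k_d / (1.0 - c_0)
    gain = prefactor * (1.0 + (f_s / kin.k_off) * (1.0 - np.exp(-2j * np.pi * f_t / f_s)))
    d_0 = kin.k_d * c_0 / (1.0 - c_0)
    return TeaFrequencyGain(f_t=f_t, f_s=f_s, gain=complex(gain), d_0=d_0)
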