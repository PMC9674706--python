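"""Closed-form design theory for pre-equilibrium sensors.

The TEA compensates the receptor's low-pass attenuation, and that same
compensation amplifies detector noise.  Integrating the squared estimator
gain over the retained band gives the noise-scaling function

    S_N(f_T, f_S) = (K_D + T_0)^2 * ( f_T*(2*f_S^2/k_off^2 + 2*f_S/k_off + 1)
                    - (f_S^2/pi)*(f_S/k_off^2 + 1/k_off)*sin(2*pi*f_T/f_S) ),

with units Hz*(M per fraction bound)^2, so that the output noise power is
N_0/2 * S_N and the estimate SNR is var(T)/(N_0/2 * S_N).  For fixed k_on,
T_0 and bandwidth, S_N has a minimum in k_off: slower receptors need more
compensation (left branch, ~T_0^2/k_off^2), while faster receptors pay the
price of a larger K_D and hence a steeper isotherm inverse (right branch,
~K_D^2 * f_T).  Their intersection yields the rule-of-thumb optimal affinity

    K_D* = sqrt(T_0 * alpha / k_on),   alpha^2 = 2*f_S^2 - f_S^3/(pi*f_T) * sin(2*pi*f_T/f_S),

which reduces to K_D* ~= 1.90*sqrt(f_T*T_0/k_on) when f_S >> f_T.  This
module evaluates these expressions, searches the true minimum, and inverts
the SNR relation into a detector noise budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._containers import DomainError, SweepRangeError
from .binding_kinetics import ReceptorKinetics

__all__ = [
    "DesignPoint",
    "OptimizationResult",
    "noise_scaling",
    "sn_asymptote_fast",
    "sn_asymptote_slow",
    "output_noise_power",
    "snr_e",
    "optimize_kd",
    "kd_star",
    "noise_budget",
    "design_sweep",
]

#: Log-grid search domain for k_off (1/s) and resolution (points per decade).
KOFF_SEARCH_RANGE = (1e-8, 1e2)
KOFF_GRID_PER_DECADE = 60


@dataclass(frozen=True)
class DesignPoint:
    """One (receptor, signal, sampling) configuration with its noise scaling."""

    kin: ReceptorKinetics
    t_0: float
    f_t: float
    f_s: float
    s_n: float
    noise_psd: float | None = None
    snr_db: float | None = None


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of minimising S_N over k_off at fixed k_on, T_0, f_T, f_S.

    ``shallow`` flags minima where S_N stays within 1% over more than a
    2-fold K_D range — there the rule-of-thumb K_D* and the true optimum can
    differ materially without costing noise performance.
    """

    koff_opt: float
    kd_opt: float
    s_n_min: float
    kd_star: float
    alpha: float
    shallow: bool


def _validate(k_off: float, f_t: float, f_s: float) -> None:
    if k_off <= 0:
        raise DomainError("k_off must be positive (zero off-rate needs infinite compensation)")
    if not 0 < f_t <= f_s / 2 + 1e-15:
        raise ValueError("need 0 < f_T <= f_S/2")


def noise_scaling(kin: ReceptorKinetics, t_0: float, f_t: float, f_s: float) -> float:
    """Noise-scaling function S_N(f_T, f_S), Hz*(M per fraction bound)^2."""
    _validate(kin.k_off, f_t, f_s)
    if t_0 < 0:
        raise DomainError("T_0 must be non-negative")
    ko = kin.k_off
    bracket = f_t * (2 * f_s**2 / ko**2 + 2 * f_s / ko + 1.0) - (
        f_s**2 / math.pi
    ) * (f_s / ko**2 + 1.0 / ko) * math.sin(2 * math.pi * f_t / f_s)
    return (kin.k_d + t_0) ** 2 * bracket


def sn_asymptote_fast(kin: ReceptorKinetics, f_t: float) -> float:
    """k_off -> infinity asymptote of S_N: (k_off/k_on)^2 * f_T."""
    return kin.k_d**2 * f_t


def sn_asymptote_slow(kin: ReceptorKinetics, t_0: float, f_t: float, f_s: float) -> float:
    """k_off -> 0 asymptote: T_0^2/k_off^2 * (2*f_S^2*f_T - f_S^3/pi * sin(2*pi*f_T/f_S))."""
    return (t_0**2 / kin.k_off**2) * (
        2 * f_s**2 * f_t - (f_s**3 / math.pi) * math.sin(2 * math.pi * f_t / f_s)
    )


def output_noise_power(noise_psd: float, s_n: float) -> float:
    """Average estimator output noise power, M^2: sigma^2_out = N_0/2 * S_N."""
    if noise_psd < 0 or s_n < 0:
        raise ValueError("inputs must be non-negative")
    return noise_psd * s_n


def snr_e(signal_var: float, noise_psd: float, s_n: float, *, as_db: bool = False) -> float:
    """Estimate SNR: var(T) / (N_0/2 * S_N), optionally in dB.

    ``signal_var`` follows the amplitude-squared convention used throughout
    the design chain: for a sinusoid of amplitude T_1, pass T_1^2.
    """
    denom = output_noise_power(noise_psd, s_n)
    if denom == 0:
        raise ZeroDivisionError("zero output noise power: SNR undefined")
    ratio = signal_var / denom
    return 10.0 * math.log10(ratio) if as_db else ratio


def kd_star(
    k_on: float,
    t_0: float,
    f_t: float,
    f_s: float | None = None,
    *,
    exact: bool = False,
) -> tuple[float, float]:
    """Rule-of-thumb optimal affinity from the asymptote intersection.

    Returns (K_D*, alpha).  The exact form is K_D* = sqrt(T_0*alpha/k_on) with
    alpha^2 = 2*f_S^2 - f_S^3/(pi*f_T)*sin(2*pi*f_T/f_S); the shortcut,
    valid for f_S >> f_T, is K_D* ~= 1.90*sqrt(f_T*T_0/k_on).  The two agree
    within 1% once f_S >= 10*f_T.
    """
    if k_on <= 0 or t_0 < 0 or f_t <= 0:
        raise ValueError("need k_on > 0, T_0 >= 0, f_T > 0")
    if exact:
        if f_s is None:
            raise ValueError("exact form needs f_S")
        alpha2 = 2 * f_s**2 - (f_s**3 / (math.pi * f_t)) * math.sin(2 * math.pi * f_t / f_s)
        alpha = math.sqrt(alpha2)
    else:
        # f_S >> f_T limit: alpha -> 2*pi*f_T/sqrt(3), i.e. K_D* ~= 1.90*sqrt(f_T*T_0/k_on)
        alpha = 1.90**2 * f_t
    return math.sqrt(t_0 * alpha / k_on), alpha


def optimize_kd(k_on: float, t_0: float, f_t: float, f_s: float) -> OptimizationResult:
    """Minimise S_N over k_off; return the optimal affinity and diagnostics.

    Log-grid bracketing (60 points per decade over 1e-8..1e2 1/s) followed by
    bounded scalar refinement.  A derivative-based search is deliberately
    avoided: the minimum is often extremely shallow.
    """
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    lo, hi = KOFF_SEARCH_RANGE
    n = int(KOFF_GRID_PER_DECADE * math.log10(hi / lo)) + 1
    grid = np.logspace(math.log10(lo), math.log10(hi), n)

    def f(log_ko: float) -> float:
        return noise_scaling(ReceptorKinetics(k_on, 10.0**log_ko), t_0, f_t, f_s)

    vals = np.array([f(lk) for lk in np.log10(grid)])
    i = int(np.argmin(vals))
    if i == 0 or i == n - 1:
        raise SweepRangeError(
            f"S_N minimum not bracketed in k_off range {KOFF_SEARCH_RANGE}"
        )
    res = minimize_scalar(
        f, bounds=(math.log10(grid[i - 1]), math.log10(grid[i + 1])),
        method="bounded", options={"xatol": 1e-4},
    )
    koff_opt = 10.0**res.x
    s_n_min = float(res.fun)

    star, alpha = kd_star(k_on, t_0, f_t, f_s, exact=True)

    # shallowness: S_N within 1% of the minimum over more than a 2x K_D span
    factors = np.logspace(-0.5, 0.5, 41)  # ~3.2x span
    within = np.array([f(math.log10(koff_opt * c)) for c in factors]) <= 1.01 * s_n_min
    span = factors[within]
    shallow = bool(within.any() and span.max() / span.min() > 2.0)
    if shallow:
        warnings.warn(
            "S_N minimum is shallow (within 1% over a >2x K_D range); "
            "K_D* and the grid optimum may differ without practical cost"
        )
    return OptimizationResult(
        koff_opt=float(koff_opt), kd_opt=float(koff_opt / k_on),
        s_n_min=s_n_min, kd_star=star, alpha=alpha, shallow=shallow,
    )


def noise_budget(
    snr_target_db: float, t_1: float, s_n: float, f_s: float
) -> tuple[float, float]:
    """Detector noise budget for a target SNR: returns (max N_0/2, max sigma).

    Inverts the SNR relation under the amplitude-squared convention:
    N_0/2 = T_1^2 / (SNR * S_N) and sigma = sqrt(f_S * N_0/2).
    """
    if not (math.isfinite(snr_target_db) and t_1 > 0 and s_n > 0 and f_s > 0):
        raise ValueError("need finite SNR target and positive T_1, S_N, f_S")
    snr = 10.0 ** (snr_target_db / 10.0)
    psd_max = t_1**2 / (snr * s_n)
    return psd_max, math.sqrt(f_s * psd_max)


def design_sweep(k_on_values, t_0_values, f_t: float, f_s: float) -> pd.DataFrame:
    """Optimal-affinity grid over (k_on, T_0); one row per design point."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k_on in np.atleast_1d(k_on_values):
            for t_0 in np.atleast_1d(t_0_values):
                r = optimize_kd(float(k_on), float(t_0), f_t, f_s)
                rows.append({
                    "k_on": float(k_on), "t_0": float(t_0), "f_t": f_t, "f_s": f_s,
                    "koff_opt": r.koff_opt, "kd_opt": r.kd_opt, "s_n_min": r.s_n_min,
                    "kd_star": r.kd_star, "alpha": r.alpha, "shallow": r.shallow,
                })
    return pd.DataFrame(rows)
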