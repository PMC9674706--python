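"""Shared time-series containers and exception types.

These are re-exported from the public modules (:mod:`preqsense.binding_kinetics`,
:mod:`preqsense.sensor_pipeline`, :mod:`preqsense.tea`); they live here only to
keep the import graph acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "SaturationError",
    "SweepRangeError",
    "BoundFractionSeries",
    "SampledTrace",
    "EstimateSeries",
]


class DomainError(ValueError):
    """An input lies outside the physical domain of the model."""


class SaturationError(DomainError):
    """Fraction bound at or above 1: the binding isotherm is not invertible."""


class SweepRangeError(RuntimeError):
    """A swept quantity did not bracket the feature being searched for."""


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class BoundFractionSeries:
    """Dense fraction-bound trajectory y(t) on a strictly increasing time grid.

    Attributes
    ----------
    t : ndarray
        Time, seconds, strictly increasing.
    y : ndarray
        Fraction of receptors bound, in [0, 1].
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = _as_1d_float(self.t, "t")
        y = _as_1d_float(self.y, "y")
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        if t.size < 2:
            raise ValueError("series needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if y.min() < -1e-9 or y.max() > 1 + 1e-9:
            raise DomainError("fraction bound outside [0, 1]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", np.clip(y, 0.0, 1.0))

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path) -> None:
        write_timeseries_csv(path, self.t, self.y, value_name="fraction_bound")

    @classmethod
    def from_csv(cls, path) -> "BoundFractionSeries":
        t, y = read_timeseries_csv(path)
        return cls(t=t, y=y)


@dataclass(frozen=True)
class SampledTrace:
    """Discrete detector output w[n] taken at a uniform sampling rate.

    After noise injection the samples may lie outside [0, 1]; the estimator
    guard policy deals with that downstream.

    Attributes
    ----------
    f_s : float
        Sampling frequency, Hz.
    w : ndarray
        Samples, fraction-bound units.
    t0 : float
        Time of the first sample, seconds.
    filtered : bool
        Whether a low-pass filter has been applied.
    cutoff : float or None
        Filter cutoff, Hz, when ``filtered``.
    warmup : int
        Number of samples at each end that are invalid after filtering.
    """

    f_s: float
    w: np.ndarray
    t0: float = 0.0
    filtered: bool = False
    cutoff: float | None = None
    warmup: int = 0

    def __post_init__(self) -> None:
        if not self.f_s > 0:
            raise ValueError("f_s must be positive")
        w = _as_1d_float(self.w, "w")
        if w.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.cutoff is not None and self.cutoff > self.f_s / 2 + 1e-12:
            raise ValueError("cutoff exceeds the Nyquist frequency")
        object.__setattr__(self, "w", w)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.w.size) / self.f_s

    def __len__(self) -> int:
        return self.w.size

    def valid_slice(self) -> slice:
        """Index range unaffected by filter edge effects."""
        return slice(self.warmup, self.w.size - self.warmup if self.warmup else None)


@dataclass(frozen=True)
class EstimateSeries:
    """Estimated target concentration E[n], molar.

    The discrete estimator needs a backward difference, so the series starts
    one sample after the input trace; ``clipped`` marks samples where the
    saturation guard was active.
    """

    t: np.ndarray
    e: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = _as_1d_float(self.t, "t")
        e = np.asarray(self.e, dtype=float)
        if t.shape != e.shape:
            raise ValueError("t and e must have the same length")
        clipped = self.clipped
        if clipped is None:
            clipped = np.zeros(t.shape, dtype=bool)
        clipped = np.asarray(clipped, dtype=bool)
        if clipped.shape != t.shape:
            raise ValueError("clipped mask length mismatch")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "clipped", clipped)

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path) -> None:
        write_timeseries_csv(path, self.t, self.e, value_name="estimate_M")


def write_timeseries_csv(path, t, value, value_name: str = "value") -> None:
    """Two-column CSV (time_s, value) with 12 significant digits."""
    df = pd.DataFrame({"time_s": np.asarray(t, float), value_name: np.asarray(value, float)})
    df.to_csv(path, index=False, float_format="%.12g")


def read_timeseries_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: file contains a header but no data rows")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(v)))
    if bad.size:
        # +2: header line plus 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: non-numeric or missing values at line(s) {lines}")
    return t, v
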