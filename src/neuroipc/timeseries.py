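"""Uniform-grid time series containers used throughout the package.

All signals in this package (neuronal activity, HRF kernels, BOLD) live on
uniform time grids in seconds.  :class:`TimeSeries` is the fine-grid container;
:class:`SampledBOLD` is the scanner-resolution container whose step is the
repetition time (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "SampledBOLD", "GridError", "time_grid"]

#: relative tolerance for deciding that two grid steps are "the same"
_GRID_RTOL = 1e-9


class GridError(ValueError):
    """Raised when time grids are non-uniform, mismatched or misaligned."""


def time_grid(duration_s: float, dt: float, t0: float = 0.0) -> np.ndarray:
    """Return a uniform grid ``t0, t0+dt, ...`` covering ``[t0, t0+duration_s]``.

    The end point is included when it falls on the grid (within rounding).
    """
    if dt <= 0:
        raise GridError(f"grid step must be positive, got dt={dt}")
    n = int(round(duration_s / dt)) + 1
    return t0 + dt * np.arange(n)


def check_uniform(t: np.ndarray) -> float:
    """Validate that ``t`` is a uniform, increasing grid; return its step."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise GridError("time grid must be a 1-D array with at least 2 points")
    steps = np.diff(t)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=_GRID_RTOL * max(abs(dt), 1.0)):
        raise GridError("time grid must be uniformly spaced and increasing")
    return float(dt)


@dataclass
class TimeSeries:
    """A real-valued signal sampled on a uniform time grid.

    Parameters
    ----------
    t0 : float
        Time of the first sample, in seconds.
    dt : float
        Sampling step, in seconds (> 0).
    values : ndarray
        Sample values; finite floats.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise GridError(f"dt must be positive, got {self.dt}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise GridError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Time spanned from the first to the last sample."""
        return self.dt * (self.values.size - 1)

    @classmethod
    def from_times(cls, t: np.ndarray, values: np.ndarray) -> "TimeSeries":
        dt = check_uniform(t)
        return cls(t0=float(t[0]), dt=dt, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "TimeSeries") -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.dt, other.dt, rtol=_GRID_RTOL)
            and np.isclose(self.t0, other.t0, rtol=0, atol=_GRID_RTOL * max(self.dt, 1.0))
        )

    def require_same_grid(self, other: "TimeSeries") -> None:
        if not self.same_grid(other):
            raise GridError("time series are not on the same grid")

    def index_of(self, t: float, *, tol: float | None = None) -> int:
        """Grid index closest to time ``t``; error if off-grid beyond ``tol``."""
        pos = (t - self.t0) / self.dt
        idx = int(round(pos))
        tol = 0.5 if tol is None else tol / self.dt
        if abs(pos - idx) > tol or idx < 0 or idx >= len(self):
            raise GridError(f"time {t} s does not fall on the grid")
        return idx


@dataclass
class SampledBOLD:
    """BOLD signal sampled at scanner resolution (one value per TR)."""

    tr: float
    values: np.ndarray = field(repr=False)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise GridError(f"tr must be positive, got {self.tr}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("BOLD values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.tr * np.arange(self.values.size)

    def as_timeseries(self) -> TimeSeries:
        return TimeSeries(t0=self.t0, dt=self.tr, values=self.values.copy())
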