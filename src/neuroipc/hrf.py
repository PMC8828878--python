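"""Canonical double-gamma hemodynamic response function (HRF).

The HRF maps neuronal activity to the BOLD signal by convolution.  The kernel
is the difference of two gamma densities,

    h(t) = A * [ g(t; alpha1, beta1) - c * g(t; alpha2, beta2) ],

where ``g(t; a, b)`` is the gamma probability density with shape ``a`` and
rate ``b``.  ``alpha1``/``alpha2`` set the delays of the positive response
lobe and the undershoot (equal to the delays in seconds when the dispersions
``beta1 = beta2 = 1``), and ``c`` is the undershoot-to-response ratio.
Because each gamma density integrates to one, the kernel integrates to
``A * (1 - c)`` exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.stats import gamma as _gamma

from .timeseries import TimeSeries, check_uniform

__all__ = [
    "HRFParams",
    "InvalidParameterError",
    "hrf_kernel",
    "hrf_integral",
    "kernel_peak",
    "peak_normalized",
    "DEFAULT_SUPPORT_S",
]

#: default kernel support; beyond this the default-shape kernel is < 1e-6 of peak
DEFAULT_SUPPORT_S = 32.0


class InvalidParameterError(ValueError):
    """Raised for HRF parameters outside their valid domain."""


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the double-gamma HRF.

    Attributes
    ----------
    A : float
        Amplitude scale (absorbs BOLD units).
    alpha1, alpha2 : float
        Shape parameters of the response and undershoot gammas (> 1, so the
        kernel is exactly zero at t = 0).
    beta1, beta2 : float
        Reciprocal dispersions (rate parameters, 1/s, > 0; default 1).
    c_ratio : float
        Undershoot-to-response ratio, in [0, 1); default 1/6.
    """

    A: float = 1.0
    alpha1: float = 6.0
    alpha2: float = 16.0
    beta1: float = 1.0
    beta2: float = 1.0
    c_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not (self.alpha1 > 1 and self.alpha2 > 1):
            raise InvalidParameterError(
                f"gamma shapes must exceed 1, got alpha1={self.alpha1}, alpha2={self.alpha2}"
            )
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise InvalidParameterError(
                f"dispersions must be positive, got beta1={self.beta1}, beta2={self.beta2}"
            )
        if not (0 <= self.c_ratio < 1):
            raise InvalidParameterError(f"c_ratio must lie in [0, 1), got {self.c_ratio}")
        if not np.isfinite(self.A):
            raise InvalidParameterError("A must be finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HRFParams":
        return cls(**json.loads(Path(path).read_text()))


def hrf_kernel(params: HRFParams, grid: np.ndarray) -> TimeSeries:
    """Evaluate the double-gamma kernel pointwise on a uniform time grid.

    The grid must start at t >= 0 with a constant positive step.  The value at
    t = 0 is exactly zero (both gamma shapes exceed 1).
    """
    grid = np.asarray(grid, dtype=float)
    dt = check_uniform(grid)
    if grid[0] < 0:
        raise InvalidParameterError("HRF grid must start at t >= 0")
    vals = params.A * (
        _gamma.pdf(grid, params.alpha1, scale=1.0 / params.beta1)
        - params.c_ratio * _gamma.pdf(grid, params.alpha2, scale=1.0 / params.beta2)
    )
    return TimeSeries(t0=float(grid[0]), dt=dt, values=vals)


def hrf_integral(params: HRFParams) -> float:
    """Closed-form integral of the kernel over [0, inf): ``A * (1 - c_ratio)``."""
    return params.A * (1.0 - params.c_ratio)


def kernel_peak(params: HRFParams, dt: float = 1e-3, support_s: float = DEFAULT_SUPPORT_S) -> tuple[float, float]:
    """Return ``(t_peak, h(t_peak))`` found on a dense grid of step ``dt``."""
    t = np.arange(0.0, support_s + dt, dt)
    h = hrf_kernel(params, t).values
    i = int(np.argmax(h))
    return float(t[i]), float(h[i])


def peak_normalized(params: HRFParams, dt: float = 1e-3) -> HRFParams:
    """Rescale ``A`` so the kernel's positive peak equals one.

    Makes the amplitude parameters of the neuronal model interpretable and
    comparable across HRF shapes.
    """
    _, peak = kernel_peak(params, dt=dt)
    if peak <= 0:
        raise InvalidParameterError("kernel has no positive peak; cannot normalize")
    return replace(params, A=params.A / peak)
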