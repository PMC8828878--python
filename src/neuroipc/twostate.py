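"""The two-state excitatory/inhibitory neuronal response family.

For a single trial with impulse information arrival, the fitted neuronal
response is a sum of three decaying exponentials sharing one decay rate
``k = p/m``:

- a primary excitatory component ``a * exp(-k t) u(t)`` — the onset response
  to the stimulus (``a = alpha/m``);
- a delayed inhibitory component ``b * exp(-k (t - T)) u(t - T0)`` — a
  negative-feedback control signal that clears the previous input;
- a secondary excitatory component ``c_amp * exp(-k (t - 2T)) u(t - T1)``.

Following the convention used for TR-sampled data, the amplitudes ``b`` and
``c_amp`` are referenced at the sampling period ``T = T_ref`` and at
``2 * T_ref`` respectively, even when the free onsets ``T0``, ``T1`` differ
from those reference times; :func:`onset_amplitudes` converts to the
amplitudes at the actual onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries, check_uniform

__all__ = ["TwoStateParams", "two_state_response"]


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state E/I response (all amplitudes are activity
    units, i.e. bits per bit of storage; times in seconds)."""

    a: float
    b: float
    c_amp: float
    k: float
    T0: float
    T1: float
    T_ref: float = 2.5

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"decay rate k must be positive, got {self.k}")
        if min(self.a, self.b, self.c_amp) < 0:
            raise ValueError("amplitudes a, b, c_amp must be >= 0")
        if self.T0 < 0 or self.T1 < 0:
            raise ValueError("onsets must be >= 0")
        if self.T0 > self.T1:
            raise ValueError(f"inhibitory onset T0={self.T0} must not exceed T1={self.T1}")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive")

    @property
    def t_const(self) -> float:
        """Time constant T_c = m/p = 1/k in seconds."""
        return 1.0 / self.k

    def onset_amplitudes(self) -> tuple[float, float]:
        """Amplitudes of the inhibitory and secondary excitatory components
        evaluated at their actual onsets T0 and T1."""
        b_on = self.b * np.exp(-self.k * (self.T0 - self.T_ref))
        c_on = self.c_amp * np.exp(-self.k * (self.T1 - 2.0 * self.T_ref))
        return float(b_on), float(c_on)


def two_state_response(params: TwoStateParams, grid: np.ndarray) -> TimeSeries:
    """Evaluate the two-state response x(t) = x_E(t) - x_I(t) on a grid."""
    grid = np.asarray(grid, dtype=float)
    dt = check_uniform(grid)
    p = params
    # a unit-step onset switches on at the first grid point at/after it; the
    # small tolerance keeps onsets that are float-noise away from a grid point
    # on the intended side (shared convention with the fitting bases)
    tol = 1e-6 * dt
    x = np.where(grid >= -tol, p.a * np.exp(-p.k * np.maximum(grid, 0.0)), 0.0)
    on0 = grid >= p.T0 - tol
    x = x - np.where(on0, p.b * np.exp(-p.k * np.where(on0, grid - p.T_ref, 0.0)), 0.0)
    on1 = grid >= p.T1 - tol
    x = x + np.where(on1, p.c_amp * np.exp(-p.k * np.where(on1, grid - 2.0 * p.T_ref, 0.0)), 0.0)
    return TimeSeries(t0=float(grid[0]), dt=dt, values=x)
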