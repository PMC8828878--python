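"""The information-processing-capacity (IPC) model of a single brain region.

A region that processes information at a maximal rate ``p`` (bit/s) and can
hold up to ``m`` bits of pending input obeys the first-order linear ODE

    dx/dt = -(p/m) x(t) + (c/m) H(t),

where ``x(t)`` is the neuronal activity (the measurable cost of storage plus
processing), ``H(t)`` is the information arrival rate (bit/s) and
``c in [0, 1]`` is the fraction of arriving information retained (c = 1:
lossless region).  The model's time constant is ``T_c = m / p``.

A step input of alpha bits (``H(t) = alpha * delta(t)``) produces the
closed-form response ``x(t) = (alpha/m) exp(-t/T_c) u(t)``: activity jumps
abruptly at stimulus onset and decays as the stored input is processed.
Stimulus-locked excitatory inputs and delayed inhibitory control signals both
enter as signed impulse trains; by linearity the total activity is the sum of
the individual exponential responses.

The same ODE, reparameterized as ``dx/dt = -sigma x + beta e(t)``, is the
single-region dynamic causal model (S-DCM); ``sigma = p/m`` identifies the
self-connectivity with the ratio of processing to storage capacity and
``beta = c/m`` with retained information per unit storage.

Everything in this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timeseries import TimeSeries, GridError, check_uniform

__all__ = [
    "IPCParams",
    "EventTrain",
    "SDCMParams",
    "InvalidParameterError",
    "InvalidEventError",
    "step_response",
    "ei_response",
    "simulate_ipc",
    "simulate_sdcm",
    "information_accounting",
    "sdcm_map",
    "sdcm_inverse",
]


class InvalidParameterError(ValueError):
    """Raised for IPC/S-DCM parameters outside their valid domain."""


class InvalidEventError(ValueError):
    """Raised for malformed event trains (negative amounts, unsorted times)."""


@dataclass(frozen=True)
class IPCParams:
    """Capacity parameters of one region.

    Attributes
    ----------
    p : float
        Processing capacity, bit/s (> 0).
    m : float
        Input storage capacity, bits (> 0).
    c_loss : float
        Retained-information fraction in [0, 1]; 1 means lossless.
    """

    p: float
    m: float
    c_loss: float = 1.0

    def __post_init__(self) -> None:
        if not (self.p > 0 and self.m > 0):
            raise InvalidParameterError(f"p and m must be positive, got p={self.p}, m={self.m}")
        if not (0.0 <= self.c_loss <= 1.0):
            raise InvalidParameterError(f"c_loss must lie in [0, 1], got {self.c_loss}")

    @property
    def k(self) -> float:
        """Decay rate p/m in 1/s."""
        return self.p / self.m

    @property
    def t_const(self) -> float:
        """Time constant T_c = m/p in seconds."""
        return self.m / self.p


def _check_events(pairs) -> list[tuple[float, float]]:
    out = []
    prev = -np.inf
    for t, amount in pairs:
        t, amount = float(t), float(amount)
        if not (np.isfinite(t) and np.isfinite(amount)):
            raise InvalidEventError("event times and amounts must be finite")
        if amount < 0:
            raise InvalidEventError(f"event amount must be >= 0 bits, got {amount}")
        if t < prev:
            raise InvalidEventError("event times must be sorted non-decreasing")
        prev = t
        out.append((t, amount))
    return out


@dataclass
class EventTrain:
    """Timed excitatory and inhibitory information deliveries, in bits.

    The information arrival rate is the formal derivative of the cumulative
    delivery: a sum of signed Dirac impulses at the listed times.
    """

    excitatory: list = field(default_factory=list)
    inhibitory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.excitatory = _check_events(self.excitatory)
        self.inhibitory = _check_events(self.inhibitory)

    def signed(self) -> list[tuple[float, float]]:
        """All events merged as (time, signed amount), sorted by time."""
        ev = [(t, a) for t, a in self.excitatory] + [(t, -a) for t, a in self.inhibitory]
        return sorted(ev, key=lambda p: p[0])

    def total_bits(self) -> float:
        """Net delivered bits (excitatory minus inhibitory)."""
        return sum(a for _, a in self.excitatory) - sum(a for _, a in self.inhibitory)

    def __add__(self, other: "EventTrain") -> "EventTrain":
        return EventTrain(
            excitatory=sorted(self.excitatory + other.excitatory),
            inhibitory=sorted(self.inhibitory + other.inhibitory),
        )


@dataclass(frozen=True)
class SDCMParams:
    """Single-region DCM parameters: self-connectivity and input strength."""

    sigma: float
    beta_in: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if self.beta_in <= 0:
            raise InvalidParameterError(f"beta_in must be positive, got {self.beta_in}")


def step_response(a0: float, k: float, grid: np.ndarray) -> TimeSeries:
    """Activity after a step input: ``x(t) = a0 * exp(-k t) * u(t)``.

    ``a0`` is the initial activity alpha/m (dimensionless, >= 0) and ``k`` the
    decay rate p/m (1/s, > 0).  ``x(0) = a0`` exactly; x vanishes for t < 0.
    """
    if k <= 0:
        raise InvalidParameterError(f"decay rate k must be positive, got {k}")
    if a0 < 0:
        raise InvalidParameterError(f"initial activity must be >= 0, got {a0}")
    grid = np.asarray(grid, dtype=float)
    dt = check_uniform(grid)
    x = np.where(grid >= 0, a0 * np.exp(-k * np.maximum(grid, 0.0)), 0.0)
    return TimeSeries(t0=float(grid[0]), dt=dt, values=x)


def ei_response(events: EventTrain, k: float, m: float, grid: np.ndarray) -> TimeSeries:
    """Closed-form activity for an excitatory/inhibitory impulse train.

    ``x(t) = sum_i (alpha_i/m) e^{-k(t - T_Ei)} u(t - T_Ei)
           - sum_j (beta_j/m)  e^{-k(t - T_Ij)} u(t - T_Ij)``.

    Linear in the event amounts; each impulse of ``a`` bits contributes a
    decaying exponential of initial height ``a/m``.
    """
    if k <= 0:
        raise InvalidParameterError(f"decay rate k must be positive, got {k}")
    if m <= 0:
        raise InvalidParameterError(f"storage capacity m must be positive, got {m}")
    grid = np.asarray(grid, dtype=float)
    dt = check_uniform(grid)
    x = np.zeros_like(grid)
    for t_ev, signed_amount in events.signed():
        tau = grid - t_ev
        x += np.where(tau >= 0, (signed_amount / m) * np.exp(-k * np.maximum(tau, 0.0)), 0.0)
    return TimeSeries(t0=float(grid[0]), dt=dt, values=x)


def simulate_ipc(
    arrival: "EventTrain | TimeSeries",
    params: IPCParams,
    grid: np.ndarray,
    x0: float = 0.0,
) -> TimeSeries:
    """Numerically integrate the IPC ODE on a uniform grid.

    The ODE is linear with constant coefficients, so each step uses the exact
    exponential propagator (no discretization error for impulse inputs; the
    sampled-rate input is treated as piecewise constant over each step).
    Impulses of ``a`` bits produce an instantaneous jump of ``c_loss * a / m``
    at their (grid-aligned) time, with x taking the post-jump value there
    (right-continuous).  Event times are snapped to the nearest grid point.
    """
    grid = np.asarray(grid, dtype=float)
    dt = check_uniform(grid)
    n = grid.size
    k = params.k
    decay = np.exp(-k * dt)

    jumps = np.zeros(n)
    drive = np.zeros(n)  # piecewise-constant H(t) in bit/s, sampled per step
    if isinstance(arrival, EventTrain):
        for t_ev, signed_amount in arrival.signed():
            idx = int(round((t_ev - grid[0]) / dt))
            if idx < 0:
                raise InvalidEventError(f"event at {t_ev} s precedes the simulation grid")
            if idx >= n:
                continue  # beyond the simulated horizon
            jumps[idx] += params.c_loss * signed_amount / params.m
    elif isinstance(arrival, TimeSeries):
        if not np.isclose(arrival.dt, dt, rtol=1e-9):
            raise GridError("sampled arrival-rate series must share the simulation grid step")
        off = int(round((arrival.t0 - grid[0]) / dt))
        for i in range(n):
            j = i - off
            if 0 <= j < len(arrival):
                drive[i] = arrival.values[j]
    else:
        raise TypeError("arrival must be an EventTrain or a sampled TimeSeries")

    # gain of a constant unit drive over one step: (c/m) * (1 - e^{-k dt}) / k
    gain = params.c_loss / params.m * (1.0 - decay) / k

    x = np.empty(n)
    cur = x0 + jumps[0]
    x[0] = cur
    for i in range(n - 1):
        cur = cur * decay + drive[i] * gain + jumps[i + 1]
        x[i + 1] = cur
    return TimeSeries(t0=float(grid[0]), dt=dt, values=x)


def simulate_sdcm(
    sdcm: SDCMParams,
    arrival: "EventTrain | TimeSeries",
    grid: np.ndarray,
    x0: float = 0.0,
) -> TimeSeries:
    """Integrate the S-DCM ODE ``dx/dt = -sigma x + beta_in e(t)``.

    Uses the same exact exponential propagator as :func:`simulate_ipc`; with
    ``sigma = p/m`` and ``beta_in = c/m`` the two simulations coincide.
    """
    # the S-DCM ODE is the IPC ODE with m := 1/beta_in, p := sigma/beta_in, c := 1
    params = IPCParams(p=sdcm.sigma / sdcm.beta_in, m=1.0 / sdcm.beta_in, c_loss=1.0)
    return simulate_ipc(arrival, params, grid, x0=x0)


def information_accounting(
    x: TimeSeries,
    arrival: EventTrain,
    params: IPCParams,
    method: str = "exponential",
) -> tuple[TimeSeries, TimeSeries, TimeSeries, TimeSeries]:
    """Decompose a simulated activity trace into the conservation-law terms.

    Returns ``(I, I_p, I_m, residual)`` where

    - ``I(t)``   cumulative delivered bits (signed; inhibition counts negative),
    - ``I_p(t)`` processed bits ``p * integral_0^t x(s) ds``,
    - ``I_m(t)`` stored bits ``m * x(t)``,
    - ``residual(t) = c_loss * I(t) - I_p(t) - I_m(t)``.

    For a lossless region the residual vanishes: all delivered information is
    either already processed or still held in storage.

    The cumulative processed information is integrated per step by the
    ``method``:

    - ``"exponential"`` (default): assumes x decays exponentially at rate
      p/m within each step — exact (to rounding) for traces produced by
      :func:`simulate_ipc` under impulse arrival, since the propagator is the
      exact exponential;
    - ``"trapezoid"``: cumulative trapezoidal quadrature of p*x (second-order
      accurate for arbitrary traces; its O(dt^2 k^2) error shows up in the
      conservation residual on coarse grids).
    """
    if method not in ("exponential", "trapezoid"):
        raise ValueError(f"unknown integration method {method!r}")
    grid = x.times
    n = len(x)
    delivered = np.zeros(n)
    for t_ev, signed_amount in arrival.signed():
        idx = int(round((t_ev - x.t0) / x.dt))
        if idx < 0:
            raise InvalidEventError(f"event at {t_ev} s precedes the series")
        if idx >= n:
            continue
        delivered[idx] += signed_amount
    i_t = np.cumsum(delivered)

    i_m = params.m * x.values
    if method == "trapezoid":
        rate = params.p * x.values
        i_p = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * x.dt)])
    else:
        # integral of x_i * exp(-k tau) over one step, times p
        k = params.k
        w = (1.0 - np.exp(-k * x.dt)) / k
        i_p = np.concatenate([[0.0], np.cumsum(params.p * x.values[:-1] * w)])
    resid = params.c_loss * i_t - i_p - i_m

    mk = lambda v: TimeSeries(t0=x.t0, dt=x.dt, values=v)
    return mk(i_t), mk(i_p), mk(i_m), mk(resid)


def sdcm_map(params: IPCParams) -> SDCMParams:
    """Map capacity parameters to the S-DCM: ``sigma = p/m``, ``beta = c/m``."""
    if params.c_loss <= 0:
        raise InvalidParameterError("c_loss must be positive to define beta_in")
    return SDCMParams(sigma=params.p / params.m, beta_in=params.c_loss / params.m)


def sdcm_inverse(sdcm: SDCMParams, c_loss: float = 1.0) -> IPCParams:
    """Recover (p, m) from S-DCM parameters, given the retained fraction."""
    if c_loss <= 0:
        raise InvalidParameterError("inverse mapping requires c_loss > 0")
    m = c_loss / sdcm.beta_in
    return IPCParams(p=sdcm.sigma * m, m=m, c_loss=c_loss)
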