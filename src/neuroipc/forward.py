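"""Forward map from neuronal activity to sampled BOLD.

BOLD is the continuous convolution of neuronal activity with the HRF,
``y(t) = x(t) * h(t)``, observed at the scanner repetition time TR with
additive measurement noise, ``y_obs = y + n``.  Activity is simulated on a
fine internal grid (default 0.1 s, 25x finer than the 2.5 s TR) so that the
discrete convolution approximates the continuous one well below fit
tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries, SampledBOLD, GridError

__all__ = ["NoiseModel", "convolve_bold", "sample_and_noise", "FINE_DT"]

#: internal fine simulation step, seconds
FINE_DT = 0.1

_NOISE_KINDS = ("none", "white-gaussian", "ar1-gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise on the sampled BOLD signal.

    ``sigma`` is the marginal standard deviation in BOLD units.  The AR(1)
    option models the temporal correlation of trial-averaged fMRI noise with
    coefficient ``rho``; innovations are scaled so the marginal SD is sigma.
    """

    kind: str = "white-gaussian"
    sigma: float = 0.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"AR(1) coefficient must satisfy |rho| < 1, got {self.rho}")

    def draw(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw ``n`` noise samples; identical seed gives identical output."""
        if self.kind == "none" or self.sigma == 0.0:
            return np.zeros(n)
        rng = np.random.default_rng(self.seed) if rng is None else rng
        if self.kind == "white-gaussian":
            return rng.normal(0.0, self.sigma, size=n)
        # stationary AR(1) with marginal SD sigma
        e = rng.normal(0.0, self.sigma * np.sqrt(1.0 - self.rho**2), size=n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, self.sigma)
        for i in range(1, n):
            out[i] = self.rho * out[i - 1] + e[i]
        return out


def convolve_bold(x: TimeSeries, h: TimeSeries) -> TimeSeries:
    """Causal discrete convolution ``y = x * h`` scaled by the grid step.

    Riemann approximation of the continuous convolution; the output has the
    length of ``x`` (the kernel tail beyond the data window is truncated).
    Signals are causal by construction, i.e. zero-padded before t = 0.
    """
    if not np.isclose(x.dt, h.dt, rtol=1e-9):
        raise GridError(f"activity and kernel steps differ: {x.dt} vs {h.dt}")
    y = np.convolve(x.values, h.values)[: len(x)] * x.dt
    return TimeSeries(t0=x.t0, dt=x.dt, values=y)


def sample_and_noise(y: TimeSeries, tr: float, noise: NoiseModel | None = None) -> SampledBOLD:
    """Decimate a fine-grid BOLD series to TR resolution and add noise.

    TR must be an integer multiple of the fine step; samples are taken at
    t0, t0 + tr, ...  Deterministic given the noise model's seed.
    """
    ratio = tr / y.dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9 * stride:
        raise GridError(f"tr={tr} is not an integer multiple of the series step {y.dt}")
    vals = y.values[::stride].copy()
    if noise is not None:
        vals = vals + noise.draw(vals.size)
    return SampledBOLD(tr=tr, values=vals, t0=y.t0)
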