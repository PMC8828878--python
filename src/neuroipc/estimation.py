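"""Fitting the two-state E/I response and deriving relative capacities.

The inversion follows the three-step procedure:

1. deconvolve the (trial-averaged) BOLD against a chosen HRF to obtain the
   neuronal response estimate ``x_est`` (``deconvolution`` module);
2. fit the two-state excitatory/inhibitory response family to ``x_est``
   (:func:`fit_two_state`), yielding alpha/m, p/m, b, c, T0, T1;
3. validate by predicting BOLD from the fitted response and scoring the mean
   squared error against the observed signal (:func:`predict_and_score`);
   both the HRF (fixed/flexible selection, :func:`select_hrf`) and — in
   :func:`invert_bold` — the final response parameters are chosen to minimize
   this BOLD-domain MSE.

All fits use a deterministic variable-projection scheme: for fixed decay rate
``k`` and onsets ``(T0, T1)`` the three amplitudes enter linearly and are
solved by non-negative least squares; ``k`` is optimized on a coarse
logarithmic grid followed by bounded 1-D minimization, and the onsets on a
coarse-to-fine grid (0.1 s resolution), ties broken toward the earliest
onsets.

Identifiability: with impulse information arrival only the ratios alpha/m and
p/m are identifiable from the response shape, so every derived quantity is
relative — p/alpha, m/alpha and the time constant T_c = m/p — normalized by
the amplitude of a designated reference condition (conventionally the
congruent condition, whose encoded input is assumed equal across groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from .deconvolution import DeconvConfig, deconvolve_ls, spline_upsample
from .forward import FINE_DT, convolve_bold
from .hrf import DEFAULT_SUPPORT_S, HRFParams, hrf_kernel
from .timeseries import GridError, SampledBOLD, TimeSeries, time_grid
from .twostate import TwoStateParams, two_state_response

__all__ = [
    "FitConfig",
    "DerivedCapacities",
    "FitResult",
    "FitError",
    "DegenerateInputError",
    "fit_two_state",
    "fit_two_state_bold",
    "fit_shared_k",
    "derive_capacities",
    "predict_and_score",
    "invert_bold",
    "select_hrf",
    "fit_group",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when no onset pair yields a converged fit."""


class DegenerateInputError(ValueError):
    """Raised for all-zero (or empty) fit targets."""


@dataclass(frozen=True)
class FitConfig:
    """Search configuration for the two-state fit.

    Onsets are searched on a grid of ``fine_step`` (default 0.1 s) within
    ``[0, 2 T_ref]`` for the inhibitory onset T0 and ``[T_ref, 4 T_ref]`` for
    the secondary excitatory onset T1 (subject to T0 <= T1), via a coarse
    pass of ``coarse_step`` followed by local refinement.  The decay rate k
    is bounded in ``k_bounds`` (1/s).
    """

    k_bounds: tuple = (0.01, 10.0)
    n_k_coarse: int = 13
    coarse_step: float = 0.5
    fine_step: float = 0.1
    refine: bool = True
    n_refine_candidates: int = 4
    t_ref: float = 2.5

    def onset_ranges(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (0.0, 2.0 * self.t_ref), (self.t_ref, 4.0 * self.t_ref)


@dataclass(frozen=True)
class DerivedCapacities:
    """Relative capacity parameters implied by a fitted response.

    ``rel_processing = p/alpha = k / a_ref`` and ``rel_storage = m/alpha =
    1 / a_ref`` are normalized by the reference condition's fitted amplitude
    ``a_ref``; ``t_const = m/p = 1/k``; ``t_peak`` is the time-to-peak of the
    predicted BOLD; ``amp_ratio`` is the incongruent/congruent amplitude
    ratio where a condition pair was fitted.
    """

    rel_processing: float
    rel_storage: float
    t_const: float
    t_peak: float = float("nan")
    amp_ratio: float = float("nan")


@dataclass
class FitResult:
    """Output of the inversion for one dataset."""

    params: TwoStateParams
    derived: DerivedCapacities
    mse: float
    x_est: TimeSeries | None = None
    y_pred: SampledBOLD | None = None
    hrf_used: HRFParams | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# variable-projection machinery


def _onset_index(onset: float, dt: float) -> int:
    """First grid index at/after the onset (tolerant of float noise)."""
    return max(0, int(np.ceil(onset / dt - 1e-6)))


class _XSpaceBasis:
    """Two-state basis evaluated directly on the fine activity grid."""

    def __init__(self, target: TimeSeries, t_ref: float):
        self.y = target.values
        self.dt = target.dt
        self.t = target.times
        self.t_ref = t_ref
        self.n = len(self.y)

    def _shifted(self, E: np.ndarray, onset: float, ref_time: float, k: float) -> np.ndarray:
        idx = _onset_index(onset, self.dt)
        col = np.zeros(self.n)
        if idx < self.n:
            col[idx:] = E[: self.n - idx] * np.exp(-k * (idx * self.dt - ref_time))
        return col

    def design(self, k: float, T0: float, T1: float) -> np.ndarray:
        E = np.exp(-k * self.t)
        e1 = E
        e2 = self._shifted(E, T0, self.t_ref, k)
        e3 = self._shifted(E, T1, 2.0 * self.t_ref, k)
        return np.column_stack([e1, -e2, e3])


class _YSpaceBasis:
    """Two-state basis pushed through the HRF and sampled at TR."""

    def __init__(self, target: SampledBOLD, hrf: HRFParams, t_ref: float, fine_dt: float = FINE_DT):
        self.y = target.values
        self.tr = target.tr
        self.t_ref = t_ref
        self.dt = fine_dt
        self.stride = int(round(target.tr / fine_dt))
        if abs(target.tr / fine_dt - self.stride) > 1e-9:
            raise GridError("tr must be an integer multiple of the fine step")
        self.n = len(target.values)
        self.fine = time_grid((self.n - 1) * target.tr, fine_dt)
        self.kern = hrf_kernel(hrf, time_grid(DEFAULT_SUPPORT_S, fine_dt))
        self._cache_k: float | None = None
        self._cache_E: np.ndarray | None = None

    def _conv_exp(self, k: float) -> np.ndarray:
        if self._cache_k != k:
            e = np.exp(-k * self.fine)
            self._cache_E = convolve_bold(TimeSeries(0.0, self.dt, e), self.kern).values
            self._cache_k = k
        return self._cache_E

    def _shifted(self, E: np.ndarray, onset: float, ref_time: float, k: float) -> np.ndarray:
        idx = _onset_index(onset, self.dt)
        col = np.zeros(E.size)
        if idx < E.size:
            col[idx:] = E[: E.size - idx] * np.exp(-k * (idx * self.dt - ref_time))
        return col[:: self.stride]

    def design(self, k: float, T0: float, T1: float) -> np.ndarray:
        E = self._conv_exp(k)
        e1 = E[:: self.stride]
        e2 = self._shifted(E, T0, self.t_ref, k)
        e3 = self._shifted(E, T1, 2.0 * self.t_ref, k)
        return np.column_stack([e1, -e2, e3])


def _onset_pairs(t0_vals, t1_vals):
    return [(float(a), float(b)) for a in t0_vals for b in t1_vals if b >= a - 1e-12]


def _vp_search(basis, cfg: FitConfig) -> tuple[TwoStateParams, dict]:
    y = basis.y
    if y.size == 0 or not np.any(y):
        raise DegenerateInputError("fit target is empty or identically zero")

    (t0_lo, t0_hi), (t1_lo, t1_hi) = cfg.onset_ranges()
    step = cfg.coarse_step
    coarse = _onset_pairs(
        np.arange(t0_lo, t0_hi + 1e-9, step), np.arange(t1_lo, t1_hi + 1e-9, step)
    )
    if not coarse:
        raise FitError("no admissible onset pair")
    k_grid = np.geomspace(cfg.k_bounds[0], cfg.k_bounds[1], cfg.n_k_coarse)
    n_eval = 0

    def _sse_k(k: float, T0: float, T1: float) -> float:
        return nnls(basis.design(k, T0, T1), y)[1]

    def _best_k_for_pair(T0: float, T1: float, xatol: float) -> tuple[float, float]:
        """Bracket k on a small log grid, then polish locally."""
        nonlocal n_eval
        sses = [_sse_k(k, T0, T1) for k in k_grid]
        n_eval += len(sses)
        i = int(np.argmin(sses))
        lo = k_grid[max(0, i - 1)]
        hi = k_grid[min(len(k_grid) - 1, i + 1)]
        if lo >= hi:
            return float(k_grid[i]), float(sses[i])
        res = minimize_scalar(
            _sse_k, args=(T0, T1), bounds=(float(lo), float(hi)),
            method="bounded", options={"xatol": xatol},
        )
        n_eval += 1
        if res.fun <= sses[i]:
            return float(res.x), float(res.fun)
        return float(k_grid[i]), float(sses[i])

    # coarse pass: every onset pair is ranked by its own near-optimal sse
    # (optimizing k per pair; a shared sparse k grid mis-ranks pairs badly
    # when the surface has aliased basins)
    per_pair = []
    for T0, T1 in coarse:
        k_best, sse = _best_k_for_pair(T0, T1, xatol=1e-3)
        per_pair.append((sse, k_best, T0, T1))

    # stable sort keeps the earliest onset pair on ties
    ranked = sorted(per_pair, key=lambda t: t[0])

    def _with_amps(k, T0, T1):
        amps, r = nnls(basis.design(k, T0, T1), y)
        return (r, k, T0, T1, amps)

    _, k_b, T0_b, T1_b = ranked[0]
    best = _with_amps(k_b, T0_b, T1_b)

    if cfg.refine:
        # refine the top candidate onset pairs (the surface is multimodal in
        # (k, T0, T1), so the runner-up basins are kept in play); each fine
        # pair gets its own bounded k search, and the winner is polished
        half = step * 0.6 + 1e-9
        for _, k_c, T0_c, T1_c in ranked[: cfg.n_refine_candidates]:
            lo = max(cfg.k_bounds[0], k_c / 4.0)
            hi = min(cfg.k_bounds[1], k_c * 4.0)
            xatol_rank = max(1e-3 * k_c, 1e-5)
            fine = _onset_pairs(
                np.arange(max(t0_lo, T0_c - half), min(t0_hi, T0_c + half) + 1e-9, cfg.fine_step),
                np.arange(max(t1_lo, T1_c - half), min(t1_hi, T1_c + half) + 1e-9, cfg.fine_step),
            )
            for T0, T1 in fine:
                res = minimize_scalar(
                    _sse_k, args=(T0, T1), bounds=(lo, hi), method="bounded",
                    options={"xatol": xatol_rank},
                )
                n_eval += 1
                if res.fun < best[0]:
                    best = _with_amps(float(res.x), T0, T1)
        # high-precision polish of k at the winning onsets
        _, k_w, T0_w, T1_w, _ = best
        res = minimize_scalar(
            _sse_k, args=(T0_w, T1_w),
            bounds=(max(cfg.k_bounds[0], k_w / 2.0), min(cfg.k_bounds[1], k_w * 2.0)),
            method="bounded", options={"xatol": 1e-9},
        )
        if res.fun <= best[0]:
            best = _with_amps(float(res.x), T0_w, T1_w)

    rnorm, k, T0, T1, amps = best
    params = TwoStateParams(
        a=float(amps[0]), b=float(amps[1]), c_amp=float(amps[2]),
        k=k, T0=T0, T1=T1, T_ref=cfg.t_ref,
    )
    diag = {"sse": float(rnorm**2), "n_evaluations": n_eval, "converged": True}
    return params, diag


# ---------------------------------------------------------------------------
# public fitting interface


def fit_two_state(x_est: TimeSeries, cfg: FitConfig | None = None) -> TwoStateParams:
    """Fit the two-state response to an estimated neuronal response.

    Minimizes the sum of squared residuals between ``x_est`` (fine grid) and
    the two-state form; this is the Step-2 fit in activity space.
    """
    cfg = cfg or FitConfig()
    params, _ = _vp_search(_XSpaceBasis(x_est, cfg.t_ref), cfg)
    return params


def fit_two_state_bold(
    y: SampledBOLD, hrf: HRFParams, cfg: FitConfig | None = None, fine_dt: float = FINE_DT
) -> tuple[TwoStateParams, dict]:
    """Fit the two-state response directly against TR-sampled BOLD.

    The model response is convolved with the HRF on the fine grid and sampled
    at TR, and the squared BOLD residual is minimized — the same MSE
    criterion used for HRF selection.  Noise-free, this recovers generating
    parameters exactly (up to onset-grid resolution).
    """
    cfg = cfg or FitConfig()
    return _vp_search(_YSpaceBasis(y, hrf, cfg.t_ref, fine_dt), cfg)


def fit_shared_k(
    targets: dict, hrf: HRFParams, cfg: FitConfig | None = None, fine_dt: float = FINE_DT
) -> dict:
    """Fit several conditions jointly with a shared decay rate k = p/m.

    ``targets`` maps condition labels to :class:`SampledBOLD` series.  The
    processing-to-storage ratio is assumed constant across conditions within
    a group (shared k and m); only amplitudes and onsets differ.  Stage 1
    fits each condition independently to fix its onsets; stage 2 optimizes a
    single shared k by bounded 1-D minimization of the pooled squared
    residual, re-solving each condition's amplitudes at every step.
    """
    cfg = cfg or FitConfig()
    bases, onsets = {}, {}
    for cond, y in targets.items():
        params, _ = fit_two_state_bold(y, hrf, cfg, fine_dt)
        bases[cond] = _YSpaceBasis(y, hrf, cfg.t_ref, fine_dt)
        onsets[cond] = (params.T0, params.T1)

    def pooled_sse(k: float) -> float:
        total = 0.0
        for cond, basis in bases.items():
            T0, T1 = onsets[cond]
            total += nnls(basis.design(k, T0, T1), basis.y)[1] ** 2
        return total

    res = minimize_scalar(
        pooled_sse, bounds=cfg.k_bounds, method="bounded", options={"xatol": 1e-9}
    )
    k = float(res.x)
    out = {}
    for cond, basis in bases.items():
        T0, T1 = onsets[cond]
        amps, _ = nnls(basis.design(k, T0, T1), basis.y)
        out[cond] = TwoStateParams(
            a=float(amps[0]), b=float(amps[1]), c_amp=float(amps[2]),
            k=k, T0=T0, T1=T1, T_ref=cfg.t_ref,
        )
    return out


def derive_capacities(
    params: TwoStateParams,
    reference_amp: float | None = None,
    t_peak: float = float("nan"),
    amp_ratio: float = float("nan"),
) -> DerivedCapacities:
    """Relative capacities implied by a fit.

    ``reference_amp`` is the fitted amplitude ``a`` of the normalization
    condition (defaults to this fit's own amplitude); the derived quantities
    are p/alpha = k/a_ref, m/alpha = 1/a_ref and T_c = 1/k.
    """
    a_ref = params.a if reference_amp is None else reference_amp
    if a_ref <= 0:
        raise ValueError(f"reference amplitude must be positive, got {a_ref}")
    return DerivedCapacities(
        rel_processing=params.k / a_ref,
        rel_storage=1.0 / a_ref,
        t_const=1.0 / params.k,
        t_peak=t_peak,
        amp_ratio=amp_ratio,
    )


def predict_and_score(
    params: TwoStateParams,
    h: HRFParams,
    y_obs: SampledBOLD,
    fine_dt: float = FINE_DT,
    reference_amp: float | None = None,
) -> FitResult:
    """Predict BOLD from fitted parameters and score the fit by MSE.

    ``y_pred`` is the fine-grid convolution of the fitted response with the
    HRF, sampled like the observation; ``mse = mean((y_obs - y_pred)^2)``.
    The time-to-peak of the predicted BOLD is located by dense-grid argmax
    (0.1 s; ties to the earliest peak).
    """
    stride = int(round(y_obs.tr / fine_dt))
    if abs(y_obs.tr / fine_dt - stride) > 1e-9:
        raise GridError("tr must be an integer multiple of the fine step")
    fine = time_grid((len(y_obs) - 1) * y_obs.tr, fine_dt)
    x_fine = two_state_response(params, fine)
    kern = hrf_kernel(h, time_grid(DEFAULT_SUPPORT_S, fine_dt))
    y_fine = convolve_bold(x_fine, kern)
    y_pred = y_fine.values[::stride]
    if y_pred.size != len(y_obs):
        raise GridError("prediction and observation lengths differ")
    mse = float(np.mean((y_obs.values - y_pred) ** 2))
    t_peak = float(fine[int(np.argmax(y_fine.values))])
    derived = derive_capacities(params, reference_amp, t_peak=t_peak)
    return FitResult(
        params=params,
        derived=derived,
        mse=mse,
        y_pred=SampledBOLD(tr=y_obs.tr, values=y_pred, t0=y_obs.t0),
        hrf_used=h,
    )


def invert_bold(
    y: SampledBOLD,
    hrf: HRFParams,
    deconv_cfg: DeconvConfig | None = None,
    fit_cfg: FitConfig | None = None,
    xspace_fit: bool = True,
    reference_amp: float | None = None,
) -> FitResult:
    """Full inversion of one (trial-averaged) BOLD series.

    Runs deconvolution (convolution-consistent operator), spline upsampling,
    the Step-2 activity-space fit (recorded in the diagnostics), and the
    final BOLD-domain fit that minimizes the prediction MSE; returns the
    scored result with the deconvolved ``x_est`` attached.
    """
    fit_cfg = fit_cfg or FitConfig()
    support = min(15.0, (len(y) - 1) * y.tr)
    deconv_cfg = deconv_cfg or DeconvConfig(support_s=support, operator="spline")
    x_tr = deconvolve_ls(y, hrf, deconv_cfg)
    x_fine = spline_upsample(x_tr, deconv_cfg.fine_dt)

    diag = {}
    if xspace_fit:
        try:
            diag["xspace_params"] = fit_two_state(x_fine, fit_cfg)
        except (DegenerateInputError, FitError) as exc:  # pragma: no cover
            diag["xspace_params"] = None
            diag["xspace_error"] = str(exc)

    params, fit_diag = fit_two_state_bold(y, hrf, fit_cfg)
    diag.update(fit_diag)
    result = predict_and_score(params, hrf, y, reference_amp=reference_amp)
    result.x_est = x_fine
    result.diagnostics = diag
    return result


def select_hrf(
    y: SampledBOLD,
    candidates: list,
    deconv_cfg: DeconvConfig | None = None,
    fit_cfg: FitConfig | None = None,
    xspace_fit: bool = False,
) -> tuple[HRFParams, FitResult]:
    """Select the HRF minimizing the BOLD-prediction MSE over a candidate grid.

    For each candidate the full deconvolve -> fit -> predict chain is run and
    the candidate with minimal MSE is returned together with its fit.
    """
    if not candidates:
        raise ValueError("HRF candidate set must be non-empty")
    best: tuple[HRFParams, FitResult] | None = None
    for h in candidates:
        res = invert_bold(y, h, deconv_cfg, fit_cfg, xspace_fit=xspace_fit)
        if best is None or res.mse < best[1].mse:
            best = (h, res)
    return best


def fit_group(
    datasets: dict,
    candidates: list,
    mode: str = "flexible",
    reference: object = None,
    fit_cfg: FitConfig | None = None,
) -> dict:
    """Fit several datasets under fixed- or flexible-HRF selection.

    ``datasets`` maps keys (e.g. ``("old", "IC")``) to BOLD series.  In
    ``flexible`` mode each dataset selects its own HRF from ``candidates``;
    in ``fixed`` mode the HRF is selected on the ``reference`` dataset
    (conventionally the oldest group's incongruent condition) and applied to
    all datasets.
    """
    if mode not in ("fixed", "flexible"):
        raise ValueError("mode must be 'fixed' or 'flexible'")
    out = {}
    if mode == "fixed":
        if reference not in datasets:
            raise ValueError(f"reference dataset {reference!r} not found")
        h_fixed, _ = select_hrf(datasets[reference], candidates, fit_cfg=fit_cfg)
        for key, y in datasets.items():
            out[key] = invert_bold(y, h_fixed, fit_cfg=fit_cfg)
    else:
        for key, y in datasets.items():
            _, res = select_hrf(y, candidates, fit_cfg=fit_cfg)
            out[key] = res
    return out
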