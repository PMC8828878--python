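"""Two-state fitting, HRF selection, derived capacities and scoring."""

import numpy as np
import pytest

import neuroipc as n
from neuroipc.estimation import (
    DegenerateInputError,
    FitConfig,
    derive_capacities,
    fit_shared_k,
    fit_two_state,
    fit_two_state_bold,
    invert_bold,
    predict_and_score,
    select_hrf,
)
from neuroipc.timeseries import SampledBOLD, TimeSeries, time_grid
from neuroipc.twostate import TwoStateParams, two_state_response

FINE = time_grid(15.0, 0.1)


class TestFitTwoState:
    @pytest.mark.parametrize(
        "truth",
        [
            TwoStateParams(a=1.0, b=0.4, c_amp=0.1, k=0.5, T0=2.5, T1=5.0),
            TwoStateParams(a=0.8, b=0.25, c_amp=0.2, k=1.2, T0=1.8, T1=4.6),
            TwoStateParams(a=1.5, b=0.6, c_amp=0.05, k=0.3, T0=3.0, T1=6.0),
        ],
    )
    def test_noise_free_self_recovery(self, truth):
        """Fitting an exactly representable response recovers its parameters."""
        x = two_state_response(truth, FINE)
        fit = fit_two_state(x)
        assert fit.k == pytest.approx(truth.k, rel=1e-3)
        assert fit.a == pytest.approx(truth.a, rel=1e-3)
        assert fit.b == pytest.approx(truth.b, rel=1e-2)
        assert abs(fit.T0 - truth.T0) <= 0.1 + 1e-9
        assert abs(fit.T1 - truth.T1) <= 0.1 + 1e-9

    def test_pure_exponential_yields_nested_model(self):
        """With no inhibition/secondary input the extra amplitudes vanish."""
        truth = TwoStateParams(a=1.0, b=0.0, c_amp=0.0, k=0.8, T0=2.5, T1=5.0)
        x = two_state_response(truth, FINE)
        fit = fit_two_state(x)
        assert fit.k == pytest.approx(0.8, rel=1e-4)
        assert fit.b <= 1e-6 and fit.c_amp <= 1e-6

    def test_noisy_decay_rate_median_error_under_ten_percent(self):
        """Monte-Carlo calibration: white noise at 2% of peak, 100 seeds."""
        truth = TwoStateParams(a=1.0, b=0.4, c_amp=0.1, k=0.5, T0=2.5, T1=5.0)
        clean = two_state_response(truth, FINE).values
        peak = np.abs(clean).max()
        cfg = FitConfig()
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = TimeSeries(0.0, 0.1, clean + rng.normal(0, 0.02 * peak, clean.size))
            fit = fit_two_state(noisy, cfg)
            errs.append(abs(fit.k - truth.k) / truth.k)
        assert np.median(errs) < 0.10

    def test_all_zero_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_two_state(TimeSeries(0.0, 0.1, np.zeros(151)))


class TestFitBoldSpace:
    def test_noise_free_exact_recovery(self, isolated_subject, unit_peak_hrf):
        para, truth, bold = isolated_subject
        irf = n.trial_average(bold, para, "IC")
        fit, diag = fit_two_state_bold(irf, unit_peak_hrf)
        tt = truth.two_state("IC")
        assert fit.k == pytest.approx(tt.k, rel=1e-4)
        assert fit.a == pytest.approx(tt.a, rel=1e-4)
        assert diag["sse"] < 1e-10

    def test_shared_k_fit_recovers_condition_amplitude_ratio(
        self, isolated_subject, unit_peak_hrf
    ):
        """C and IC share p/m; the fitted amplitude ratio is alpha_IC/alpha_C."""
        para, truth, bold = isolated_subject
        irfs = {c: n.trial_average(bold, para, c) for c in ("C", "IC")}
        params = fit_shared_k(irfs, unit_peak_hrf)
        assert params["C"].k == params["IC"].k
        ratio = params["IC"].a / params["C"].a
        assert ratio == pytest.approx(truth.alpha["IC"] / truth.alpha["C"], rel=1e-3)
        assert params["IC"].a > params["C"].a  # higher load, higher activity


class TestDeriveCapacities:
    def test_relative_capacity_algebra(self):
        """p/alpha = k/a, m/alpha = 1/a, T_c = 1/k with alpha as reference."""
        params = TwoStateParams(a=2.0, b=0.0, c_amp=0.0, k=1.0, T0=0.0, T1=2.5)
        d = derive_capacities(params)
        assert d.rel_processing == 0.5
        assert d.rel_storage == 0.5
        assert d.t_const == 1.0

    def test_time_constant_invariant_to_amplitude_scaling(self):
        p1 = TwoStateParams(a=1.0, b=0.0, c_amp=0.0, k=0.7, T0=0.0, T1=2.5)
        p2 = TwoStateParams(a=2.0, b=0.0, c_amp=0.0, k=0.7, T0=0.0, T1=2.5)
        d1 = derive_capacities(p1, reference_amp=1.0)
        d2 = derive_capacities(p2, reference_amp=2.0)
        assert d1.t_const == d2.t_const

    def test_nonpositive_reference_rejected(self):
        params = TwoStateParams(a=1.0, b=0.0, c_amp=0.0, k=1.0, T0=0.0, T1=2.5)
        with pytest.raises(ValueError):
            derive_capacities(params, reference_amp=0.0)


class TestPredictAndScore:
    def test_self_consistent_prediction_has_negligible_mse(self, unit_peak_hrf):
        params = TwoStateParams(a=1.0, b=0.4, c_amp=0.1, k=0.5, T0=2.5, T1=5.0)
        ref = predict_and_score(params, unit_peak_hrf, SampledBOLD(tr=2.5, values=np.zeros(13)))
        res = predict_and_score(params, unit_peak_hrf, ref.y_pred)
        assert res.mse <= 1e-12

    def test_mse_matches_elementwise_oracle(self, unit_peak_hrf):
        rng = np.random.default_rng(6)
        params = TwoStateParams(a=1.0, b=0.4, c_amp=0.1, k=0.5, T0=2.5, T1=5.0)
        y_obs = SampledBOLD(tr=2.5, values=rng.normal(size=13))
        res = predict_and_score(params, unit_peak_hrf, y_obs)
        oracle = sum((a - b) ** 2 for a, b in zip(y_obs.values, res.y_pred.values)) / 13
        assert res.mse == pytest.approx(oracle, rel=1e-12)

    def test_mse_invariant_to_common_time_shift(self, unit_peak_hrf):
        params = TwoStateParams(a=1.0, b=0.4, c_amp=0.1, k=0.5, T0=2.5, T1=5.0)
        rng = np.random.default_rng(7)
        vals = rng.normal(size=13)
        m0 = predict_and_score(params, unit_peak_hrf, SampledBOLD(tr=2.5, values=vals, t0=0.0))
        m5 = predict_and_score(params, unit_peak_hrf, SampledBOLD(tr=2.5, values=vals, t0=5.0))
        assert m0.mse == m5.mse


class TestSelectHRF:
    def test_single_candidate_is_returned(self, isolated_subject, unit_peak_hrf):
        para, _, bold = isolated_subject
        irf = n.trial_average(bold, para, "IC")
        h, res = select_hrf(irf, [unit_peak_hrf])
        assert h == unit_peak_hrf
        assert res.mse >= 0.0

    def test_generating_response_delay_identified(self, isolated_subject, unit_peak_hrf):
        """On noise-free data generated with alpha1 = 6, the grid {4..8}
        selects alpha1 = 6, and the winner's MSE is the grid minimum."""
        from dataclasses import replace

        para, _, bold = isolated_subject
        irf = n.trial_average(bold, para, "IC")
        candidates = [
            n.peak_normalized(replace(n.HRFParams(), alpha1=a1)) for a1 in (4, 5, 6, 7, 8)
        ]
        h_best, res_best = select_hrf(irf, candidates)
        assert h_best == candidates[2]
        for h in candidates:
            other = invert_bold(irf, h, xspace_fit=False)
            assert res_best.mse <= other.mse + 1e-15

    def test_empty_candidate_set_rejected(self, isolated_subject):
        para, _, bold = isolated_subject
        with pytest.raises(ValueError):
            select_hrf(n.trial_average(bold, para, "IC"), [])


class TestInvertBold:
    def test_records_xspace_estimate_and_xest_series(self, isolated_subject, unit_peak_hrf):
        para, _, bold = isolated_subject
        irf = n.trial_average(bold, para, "C")
        res = invert_bold(irf, unit_peak_hrf, xspace_fit=True)
        assert res.x_est is not None and res.x_est.dt == pytest.approx(0.1)
        assert isinstance(res.diagnostics.get("xspace_params"), TwoStateParams)
        assert res.y_pred is not None and len(res.y_pred) == len(irf)
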