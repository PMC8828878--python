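"""IPC dynamics: closed forms, ODE oracles, conservation and the S-DCM map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from neuroipc.dynamics import (
    EventTrain,
    IPCParams,
    InvalidEventError,
    InvalidParameterError,
    SDCMParams,
    ei_response,
    information_accounting,
    sdcm_inverse,
    sdcm_map,
    simulate_ipc,
    simulate_sdcm,
    step_response,
)
from neuroipc.timeseries import TimeSeries, time_grid


class TestStepResponse:
    def test_initial_value_is_alpha_over_m(self):
        """An impulse of alpha bits jumps the activity to alpha/m at t = 0."""
        x = step_response(a0=0.75, k=1.3, grid=time_grid(10.0, 0.1))
        assert x.values[0] == 0.75

    def test_decay_to_1_over_e_at_time_constant(self):
        x = step_response(a0=1.0, k=0.5, grid=time_grid(10.0, 0.1))
        assert x.values[x.index_of(2.0)] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_matches_ode_integration_with_impulse_in_initial_condition(self):
        grid = time_grid(20.0, 0.01)
        a0, k = 0.8, 0.4
        x = step_response(a0, k, grid)
        sol = solve_ivp(
            lambda t, y: -k * y, (0.0, 20.0), [a0], t_eval=grid,
            rtol=1e-12, atol=1e-14, method="LSODA",
        )
        assert np.max(np.abs(x.values - sol.y[0])) < 1e-8

    def test_invalid_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            step_response(1.0, 0.0, time_grid(5.0, 0.1))


class TestEIResponse:
    def test_two_state_difference(self):
        """x = x_E - x_I for an excitatory impulse at 0, inhibitory at T0."""
        grid = time_grid(20.0, 0.05)
        k, m, alpha, beta, T0 = 0.6, 2.0, 1.0, 0.4, 2.5
        ev = EventTrain(excitatory=[(0.0, alpha)], inhibitory=[(T0, beta)])
        x = ei_response(ev, k, m, grid)
        xe = step_response(alpha / m, k, grid).values
        xi = np.where(grid >= T0, (beta / m) * np.exp(-k * np.maximum(grid - T0, 0)), 0.0)
        np.testing.assert_allclose(x.values, xe - xi, atol=1e-14)

    def test_exact_cancellation(self):
        ev = EventTrain(excitatory=[(0.0, 0.9)], inhibitory=[(0.0, 0.9)])
        x = ei_response(ev, k=1.0, m=1.5, grid=time_grid(10.0, 0.1))
        assert np.all(x.values == 0.0)

    def test_superposition_of_step_responses(self):
        """Three events superpose linearly (brute-force superposition oracle)."""
        rng = np.random.default_rng(7)
        grid = time_grid(30.0, 0.1)
        k, m = 0.7, 2.0
        times = np.sort(rng.uniform(0, 10, 3))
        amounts = rng.uniform(0.1, 2.0, 3)
        ev = EventTrain(excitatory=[(t, a) for t, a in zip(times, amounts)])
        x = ei_response(ev, k, m, grid)
        acc = np.zeros_like(grid)
        for t, a in zip(times, amounts):
            acc += np.where(grid >= t, (a / m) * np.exp(-k * np.maximum(grid - t, 0)), 0.0)
        np.testing.assert_allclose(x.values, acc, atol=1e-12)

    def test_negative_amount_rejected(self):
        with pytest.raises(InvalidEventError):
            EventTrain(excitatory=[(0.0, -1.0)])

    def test_unsorted_times_rejected(self):
        with pytest.raises(InvalidEventError):
            EventTrain(excitatory=[(2.0, 1.0), (1.0, 1.0)])


class TestSimulateIPC:
    def test_single_impulse_equals_step_response(self):
        grid = time_grid(20.0, 0.01)
        params = IPCParams(p=1.0, m=2.0)
        ev = EventTrain(excitatory=[(0.0, 1.5)])
        x = simulate_ipc(ev, params, grid)
        ref = step_response(1.5 / 2.0, params.k, grid)
        np.testing.assert_allclose(x.values, ref.values, atol=1e-14)

    def test_total_loss_gives_zero_activity(self):
        grid = time_grid(20.0, 0.01)
        params = IPCParams(p=1.0, m=2.0, c_loss=0.0)
        ev = EventTrain(excitatory=[(0.0, 1.5), (5.0, 2.0)])
        x = simulate_ipc(ev, params, grid)
        assert np.all(x.values == 0.0)

    def test_constant_drive_converges_to_fixed_point(self):
        """dx/dt = 0 at x* = c H0 / p for a constant arrival rate."""
        grid = time_grid(80.0, 0.01)
        params = IPCParams(p=1.3, m=2.0, c_loss=0.8)
        H0 = 0.9
        drive = TimeSeries(0.0, 0.01, np.full(grid.size, H0))
        x = simulate_ipc(drive, params, grid)
        assert abs(x.values[-1] - params.c_loss * H0 / params.p) < 1e-6

    def test_agrees_with_stiff_ode_oracle_on_random_draws(self):
        """Exact-propagator integration vs generic stiff solver, 20 draws."""
        rng = np.random.default_rng(42)
        grid = time_grid(15.0, 0.01)
        for _ in range(20):
            p = float(rng.uniform(0.2, 5.0))
            m = float(rng.uniform(0.5, 5.0))
            alpha = float(rng.uniform(0.2, 3.0))
            params = IPCParams(p=p, m=m)
            x = simulate_ipc(EventTrain(excitatory=[(0.0, alpha)]), params, grid)
            sol = solve_ivp(
                lambda t, y: -(p / m) * y, (0.0, 15.0), [alpha / m], t_eval=grid,
                rtol=1e-10, atol=1e-13, method="Radau",
            )
            assert np.max(np.abs(x.values - sol.y[0])) < 1e-8

    def test_linearity_in_event_trains(self):
        grid = time_grid(30.0, 0.05)
        params = IPCParams(p=0.9, m=1.7)
        t1 = EventTrain(excitatory=[(0.0, 1.0)], inhibitory=[(2.5, 0.3)])
        t2 = EventTrain(excitatory=[(5.0, 0.7)])
        x12 = simulate_ipc(t1 + t2, params, grid)
        x1 = simulate_ipc(t1, params, grid)
        x2 = simulate_ipc(t2, params, grid)
        np.testing.assert_allclose(x12.values, x1.values + x2.values, atol=1e-12)


class TestInformationAccounting:
    @pytest.mark.parametrize("c_loss", [1.0, 0.5])
    def test_conservation_residual_bounded(self, c_loss):
        """c I(t) = I_p(t) + I_m(t) along the whole trajectory."""
        alpha = 2.0
        params = IPCParams(p=1.0, m=2.0, c_loss=c_loss)
        grid = time_grid(60.0, 0.005)
        ev = EventTrain(excitatory=[(0.0, alpha)])
        x = simulate_ipc(ev, params, grid)
        _, _, _, resid = information_accounting(x, ev, params)
        assert np.max(np.abs(resid.values)) <= 1e-6 * alpha

    def test_finite_input_is_fully_processed(self):
        """As t -> inf, I_p -> alpha and the stored amount I_m -> 0."""
        alpha = 2.0
        params = IPCParams(p=1.0, m=2.0)
        grid = time_grid(80.0, 0.005)
        ev = EventTrain(excitatory=[(0.0, alpha)])
        x = simulate_ipc(ev, params, grid)
        _, i_p, i_m, _ = information_accounting(x, ev, params)
        assert i_p.values[-1] == pytest.approx(alpha, abs=1e-5)
        assert abs(i_m.values[-1]) < 1e-12


class TestSDCM:
    def test_mapping_arithmetic(self):
        sd = sdcm_map(IPCParams(p=2.0, m=4.0, c_loss=1.0))
        assert sd.sigma == 0.5 and sd.beta_in == 0.25

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.01, 100.0),
        m=st.floats(0.01, 100.0),
        c_loss=st.floats(0.01, 1.0),
    )
    def test_round_trip_is_identity(self, p, m, c_loss):
        params = IPCParams(p=p, m=m, c_loss=c_loss)
        back = sdcm_inverse(sdcm_map(params), c_loss=c_loss)
        assert back.p == pytest.approx(p, rel=1e-12)
        assert back.m == pytest.approx(m, rel=1e-12)

    def test_inverse_requires_retained_information(self):
        with pytest.raises(InvalidParameterError):
            sdcm_inverse(SDCMParams(sigma=1.0, beta_in=0.5), c_loss=0.0)

    def test_sdcm_simulation_reproduces_ipc(self):
        """The two ODEs are algebraically identical under the mapping."""
        grid = time_grid(30.0, 0.05)
        params = IPCParams(p=1.4, m=2.3, c_loss=0.9)
        ev = EventTrain(excitatory=[(0.0, 1.2), (7.5, 0.6)], inhibitory=[(2.5, 0.4)])
        x_ipc = simulate_ipc(ev, params, grid)
        x_sdcm = simulate_sdcm(sdcm_map(params), ev, grid)
        assert np.max(np.abs(x_ipc.values - x_sdcm.values)) <= 1e-12


class TestMonotonicity:
    def test_time_constant_and_steady_state_decrease_in_p(self):
        """Higher processing capacity means faster decay and lower activity."""
        m, H0, c = 2.0, 1.0, 1.0
        ps = np.linspace(0.2, 5.0, 20)
        t_cs = [IPCParams(p=p, m=m).t_const for p in ps]
        steady = [c * H0 / p for p in ps]
        assert np.all(np.diff(t_cs) < 0)
        assert np.all(np.diff(steady) < 0)

    def test_peak_activity_decreases_in_m(self):
        """Larger storage capacity alleviates the activity demand."""
        alpha, p = 1.0, 1.0
        grid = time_grid(10.0, 0.1)
        peaks = []
        for m in np.linspace(0.5, 5.0, 10):
            x = simulate_ipc(EventTrain(excitatory=[(0.0, alpha)]), IPCParams(p=p, m=m), grid)
            peaks.append(np.max(x.values))
        assert np.all(np.diff(peaks) < 0)
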