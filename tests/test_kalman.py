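"""Adaptive Kalman filter tests, including an independent textbook-KF oracle."""

import numpy as np
import pytest

from respgate.kalman import (FilterConfig, FilterState, ModelMatrices,
                             build_process_noise, build_transition,
                             estimate_frequency, estimate_measurement_noise,
                             multi_step_predict, predict_step, run_filter,
                             update_step)
from respgate.signal import Signal
from respgate.synthetic import SimulationSpec, add_noise, gen_sine


def textbook_kf_step(x, P, A, Q, H, R, z):
    """Independent plain-vanilla Kalman predict+update (no Joseph form)."""
    x_pred = A @ x
    P_pred = A @ P @ A.T + Q
    S = H @ P_pred @ H.T + R
    K = P_pred @ H.T / S
    x_new = x_pred + K * (z - H @ x_pred)
    P_new = (np.eye(len(x)) - np.outer(K, H)) @ P_pred
    return x_pred, P_pred, x_new, P_new


def make_matrices(f_r=0.2, dt=0.01, R=0.09, Q=None):
    A = build_transition(f_r, dt)
    if Q is None:
        Q = np.zeros((3, 3))
    return ModelMatrices(A=A, Q=Q, R=R)


class TestBuildTransition:
    def test_arithmetic_entries(self):
        A = build_transition(0.2, 0.01)
        omega = 2 * np.pi * 0.2
        assert omega == pytest.approx(1.256637, abs=1e-6)
        assert A[1, 0] == pytest.approx(-omega**2 * 0.01, abs=1e-9)
        assert A[1, 0] == pytest.approx(-0.0157914, abs=1e-6)
        assert A[0, 1] == 0.01
        # structural zeros and baseline row
        assert A[0, 2] == A[1, 2] == A[2, 0] == A[2, 1] == 0.0
        assert A[2, 2] == 1.0

    def test_zero_dt_is_identity(self):
        assert np.array_equal(build_transition(0.7, 0.0), np.eye(3))

    def test_oscillator_block_eigenvalues(self):
        # eigenvalues of the (Xr, Vr) block vs brute-force decomposition
        omega = 2 * np.pi * 0.2
        dt = 0.01
        A = build_transition(0.2, dt)
        eig = np.linalg.eigvals(A[:2, :2])
        assert np.abs(eig) == pytest.approx(np.sqrt(1 + omega**2 * dt**2), abs=1e-12)


class TestPredictUpdate:
    def test_zero_state_stays_zero(self):
        st = FilterState(np.zeros(3), np.eye(3), 0.2)
        out = predict_step(st, make_matrices())
        assert np.array_equal(out.x, np.zeros(3))

    def test_velocity_moves_position(self):
        st = FilterState([0.0, 3.0, 0.0], np.eye(3), 0.2)
        out = predict_step(st, make_matrices())
        assert out.x[0] == pytest.approx(3.0 * 0.01)

    def test_covariance_propagation_matches_oracle(self):
        M = make_matrices()
        st = FilterState(np.zeros(3), np.eye(3), 0.2)
        out = predict_step(st, M)
        assert np.allclose(out.P, M.A @ M.A.T, atol=1e-12)

    def test_update_matches_textbook_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(3)
            L = rng.standard_normal((3, 3))
            P = L @ L.T + 0.1 * np.eye(3)
            z = rng.standard_normal()
            M = make_matrices(R=0.5, Q=np.diag(rng.uniform(0, 1, 3)))
            st = FilterState(x, P, 0.2)
            ours = update_step(predict_step(st, M), z, M)
            _, _, x_ref, P_ref = textbook_kf_step(x, P, M.A, M.Q,
                                                  M.H_obs, M.R, z)
            assert np.allclose(ours.x, x_ref, atol=1e-9)
            assert np.allclose(ours.P, P_ref, atol=1e-9)

    def test_huge_R_ignores_measurement(self):
        st = FilterState([1.0, 2.0, 3.0], 1e-6 * np.eye(3), 0.2)
        M = make_matrices(R=1e12)
        pred = predict_step(st, M)
        out = update_step(pred, 100.0, M)
        assert np.allclose(out.x, pred.x, atol=1e-6)

    def test_small_R_measurement_dominates(self):
        st = FilterState(np.zeros(3), 1e6 * np.eye(3), 0.2)
        M = make_matrices(R=1e-9)
        out = update_step(st, 7.0, M)
        assert out.x[0] + out.x[2] == pytest.approx(7.0, abs=1e-6)

    def test_nonpositive_R_rejected(self):
        with pytest.raises(ValueError):
            make_matrices(R=0.0)


class TestAdaptiveEstimators:
    def test_frequency_of_pure_sine(self):
        sig = gen_sine(SimulationSpec(pattern="sine", period_s=4.0, duration_s=20.0))
        cfg = FilterConfig()
        # large n_steps lets the IIR settle fully onto the raw estimate
        f = estimate_frequency(sig, cfg, prev_f=0.2, n_steps=10**6)
        assert f == pytest.approx(0.25, abs=0.01)

    def test_constant_signal_returns_previous(self):
        sig = Signal(0.0, 0.01, np.full(2000, 3.0))
        f = estimate_frequency(sig, FilterConfig(), prev_f=0.31)
        assert f == 0.31

    def test_step_response_monotone_toward_new_frequency(self):
        cfg = FilterConfig()
        new = gen_sine(SimulationSpec(pattern="sine", period_s=1 / 0.3,
                                      duration_s=20.0))
        f = 0.2
        history = []
        for _ in range(100):
            f = estimate_frequency(new, cfg, prev_f=f, n_steps=100)
            history.append(f)
        diffs = np.diff(history)
        assert np.all(diffs >= -1e-12)
        assert history[-1] == pytest.approx(0.3, abs=0.01)

    def test_noise_sd_recovered_from_white_noise(self):
        rng = np.random.default_rng(7)
        sig = Signal(0.0, 0.01, 3.0 + 0.5 * rng.standard_normal(2000))
        est = estimate_measurement_noise(sig, FilterConfig())
        assert est == pytest.approx(0.5, rel=0.1)

    def test_noise_free_sine_gives_small_residual(self):
        sig = gen_sine(SimulationSpec(pattern="sine", duration_s=10.0))
        est = estimate_measurement_noise(sig, FilterConfig())
        assert est <= 0.1

    def test_flat_buffer_returns_floor(self):
        sig = Signal(0.0, 0.01, np.full(100, 2.0))
        assert estimate_measurement_noise(sig, FilterConfig()) == pytest.approx(1e-6)

    def test_short_buffer_returns_previous(self):
        sig = Signal(0.0, 0.01, np.arange(5.0))
        assert estimate_measurement_noise(sig, FilterConfig(), prev=0.42) == 0.42


class TestProcessNoise:
    def test_arithmetic(self):
        Q = build_process_noise(1.2566, 25.0, FilterConfig())
        assert np.diag(Q) == pytest.approx([1.0, 1.5791, 0.25], abs=1e-4)
        assert np.count_nonzero(Q - np.diag(np.diag(Q))) == 0

    def test_zero_resp_variance(self):
        Q = build_process_noise(1.0, 0.0)
        assert Q[2, 2] == 0.0

    def test_default_alpha(self):
        assert FilterConfig().alpha == 0.01


class TestMultiStepPredict:
    def test_zero_state_all_zero(self):
        st = FilterState(np.zeros(3), np.eye(3), 0.2)
        assert np.array_equal(multi_step_predict(st, make_matrices(), 14),
                              np.zeros(14))

    def test_matches_matrix_power_oracle(self):
        st = FilterState([2.0, -1.0, 0.5], np.eye(3), 0.2)
        M = make_matrices()
        pred = multi_step_predict(st, M, 5)
        oracle = [(np.linalg.matrix_power(M.A, h) @ st.x)[0] for h in range(1, 6)]
        assert np.allclose(pred, oracle, atol=1e-12)

    def test_converged_filter_predicts_sine(self):
        sig = gen_sine(SimulationSpec(pattern="sine", duration_s=60.0))
        trace = run_filter(sig, FilterConfig())
        k = 4000  # settled
        truth = sig.values
        for h in range(1, 15):
            pred = trace.pred_x[k, h - 1] + trace.c[k]
            assert abs(pred - truth[k + h]) < 0.2


class TestRunFilter:
    def test_noise_free_sine_steady_state(self):
        sig = gen_sine(SimulationSpec(pattern="sine", duration_s=30.0))
        trace = run_filter(sig, FilterConfig())
        err = np.abs(trace.filtered - sig.values)[1000:]  # after 2 cycles
        assert err.max() < 0.05

    def test_filter_reduces_noise_rmse(self):
        truth = gen_sine(SimulationSpec(pattern="sine", duration_s=60.0))
        meas = add_noise(truth, 0.5, seed=3)
        trace = run_filter(meas, FilterConfig())
        rmse_raw = np.sqrt(np.mean((meas.values - truth.values)[1000:] ** 2))
        rmse_filt = np.sqrt(np.mean((trace.filtered - truth.values)[1000:] ** 2))
        assert rmse_filt < rmse_raw

    def test_determinism(self):
        truth = gen_sine(SimulationSpec(pattern="sine", duration_s=20.0))
        meas = add_noise(truth, 0.3, seed=5)
        a = run_filter(meas, FilterConfig())
        b = run_filter(meas, FilterConfig())
        assert np.array_equal(a.xr, b.xr)
        assert np.array_equal(a.pred_x, b.pred_x)

    def test_causality_truncation_reproduces_prefix(self):
        truth = gen_sine(SimulationSpec(pattern="sine", duration_s=40.0))
        meas = add_noise(truth, 0.3, seed=6)
        full = run_filter(meas, FilterConfig())
        part = run_filter(Signal(meas.t0, meas.dt, meas.values[:2500]),
                          FilterConfig())
        assert np.array_equal(part.xr, full.xr[:2500])
        assert np.array_equal(part.pred_x, full.pred_x[:2500])

    def test_covariance_health_every_step(self):
        truth = gen_sine(SimulationSpec(pattern="sine", duration_s=30.0))
        meas = add_noise(truth, 0.3, seed=8)
        trace = run_filter(meas, FilterConfig(), collect_P=True)
        asym = np.max(np.abs(trace.P_full - trace.P_full.transpose(0, 2, 1)))
        assert asym <= 1e-9
        assert np.linalg.eigvalsh(trace.P_full).min() >= -1e-9

    def test_frequency_recovery_two_percent(self):
        for f in (0.17, 0.2, 0.33):
            truth = gen_sine(SimulationSpec(pattern="sine", period_s=1 / f,
                                            duration_s=60.0))
            meas = add_noise(truth, 0.3, seed=11)
            trace = run_filter(meas, FilterConfig())
            assert trace.fr[-1] == pytest.approx(f, rel=0.02)

    def test_nan_input_rejected_with_index(self):
        sig = Signal(0.0, 0.01, np.ones(100))
        sig.values[37] = np.nan  # bypasses construction check on purpose
        with pytest.raises(ValueError, match="37"):
            run_filter(sig, FilterConfig())

    def test_discretization_limit_single_step(self):
        # exact oscillator state stepped through A vs closed-form sine
        # propagation: per-step error is O(dt^2)
        A_mm, T = 10.0, 5.0
        omega = 2 * np.pi / T
        dt = 0.01
        Atr = build_transition(1 / T, dt)
        for phase in np.linspace(0, 2 * np.pi, 17):
            x = np.array([A_mm * np.sin(phase), A_mm * omega * np.cos(phase), 0.0])
            stepped = Atr @ x
            closed = A_mm * np.sin(phase + omega * dt)
            assert abs(stepped[0] - closed) < 10 * A_mm * omega**2 * dt**2
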