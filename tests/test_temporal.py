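import numpy as np
import pytest
from scipy.optimize import nnls

from cnmfe.temporal import (
    ARModel,
    ar_impulse_response,
    deconvolve_trace,
    fit_ar_coefficients,
    oasis_ar1,
    project_residual_trace,
    update_temporal,
)


def qp_oracle_ar1(y, gamma, lam):
    """Brute-force QP for the L1-penalised AR(1) problem via an exact NNLS
    reduction: K lower-triangular Toeplitz of the impulse response,
    0.5||Ks-y||^2 + lam 1's == 0.5||Ks-z||^2 + const with
    z = y - lam K^{-T} 1."""
    T = len(y)
    h = ar_impulse_response([gamma], T)
    K = np.zeros((T, T))
    for j in range(T):
        K[j:, j] = h[: T - j]
    z = y - lam * np.linalg.solve(K.T, np.ones(T))
    s, _ = nnls(K, z)
    c = K @ s
    return 0.5 * ((c - y) ** 2).sum() + lam * s.sum()


class TestOasis:
    def test_zero_input_gives_zero(self):
        c, s = oasis_ar1(np.zeros(20), 0.9)
        assert np.all(c == 0) and np.all(s == 0)

    def test_noiseless_single_spike_recovered(self):
        T, g, t0 = 60, 0.85, 17
        h = ar_impulse_response([g], T)
        y = np.zeros(T)
        y[t0:] = h[: T - t0] * 2.5
        c, s = oasis_ar1(y, g)
        assert np.allclose(c, y, atol=1e-9)
        assert np.flatnonzero(s > 1e-9).tolist() == [t0]
        assert s[t0] == pytest.approx(2.5, abs=1e-9)

    def test_matches_qp_oracle_on_random_instances(self, rng):
        worst = 0.0
        for _ in range(60):
            T = int(rng.integers(5, 31))
            g = float(rng.uniform(0.3, 0.98))
            lam = float(rng.uniform(0.0, 1.0))
            h = ar_impulse_response([g], T)
            spikes = (rng.random(T) < 0.1) * rng.uniform(1, 3)
            y = np.convolve(spikes, h)[:T] + 0.5 * rng.standard_normal(T)
            c, s = oasis_ar1(y, g, lam=lam)
            obj = 0.5 * ((c - y) ** 2).sum() + lam * s.sum()
            worst = max(worst, obj - qp_oracle_ar1(y, g, lam))
        assert worst < 1e-6

    def test_constraint_satisfied(self, rng):
        y = rng.standard_normal(200)
        g = 0.9
        c, s = oasis_ar1(y, g, lam=0.1)
        assert np.all(s >= -1e-10)
        assert np.all(c >= -1e-12)
        # s = G c within tolerance
        assert np.allclose(s[1:], c[1:] - g * c[:-1], atol=1e-10)


class TestARFit:
    def test_ar1_coefficient_recovered(self, rng):
        g, T = 0.9, 5000
        s = (rng.random(T) < 0.05) * 1.0
        c = np.zeros(T)
        for t in range(1, T):
            c[t] = g * c[t - 1] + s[t]
        y = c + 0.1 * rng.standard_normal(T)
        ar = fit_ar_coefficients(y, 1, 0.1)
        assert 0.85 <= ar.coefficients[0] <= 0.95

    def test_double_exponential_kernel_round_trip(self, rng):
        from cnmfe.simulate import calcium_kernel

        tau_d, tau_r, T = 6.0, 1.0, 10000
        g_true = np.array([np.exp(-1 / tau_d) + np.exp(-1 / tau_r),
                           -np.exp(-1 / tau_d) * np.exp(-1 / tau_r)])
        spikes = (rng.random(T) < 0.02) * 1.0
        c = np.convolve(spikes, calcium_kernel(tau_d, tau_r, T))[:T]
        y = c + 0.01 * rng.standard_normal(T)
        ar = fit_ar_coefficients(y, 2, 0.01)
        h_est = ar_impulse_response(ar.coefficients, 200)
        h_true = ar_impulse_response(g_true, 200)
        diff = np.linalg.norm(h_est / np.linalg.norm(h_est)
                              - h_true / np.linalg.norm(h_true))
        assert diff < 0.05

    def test_white_noise_gives_zero_dynamics(self, rng):
        y = rng.standard_normal(2000)
        ar = fit_ar_coefficients(y, 2, 1.0)
        assert np.allclose(ar.coefficients, 0.0)
        h = ar.impulse_response(10)
        assert h[0] == 1.0 and np.all(h[1:] == 0)


class TestDeconvolveTrace:
    def test_zero_trace(self):
        ar = ARModel(np.array([0.9]))
        c, s, b = deconvolve_trace(np.zeros(50), ar, 0.1, optimize_baseline=False)
        assert np.all(c == 0) and np.all(s == 0)

    def test_noiseless_spike_train_ar2(self, rng):
        g = np.array([1.2, -0.3])
        ar = ARModel(g)
        T = 300
        h = ar.impulse_response(T)
        s_true = np.zeros(T)
        s_true[[40, 120, 200]] = [2.0, 1.5, 3.0]
        y = np.convolve(s_true, h)[:T]
        c, s, b = deconvolve_trace(y, ar, 1e-4, optimize_baseline=False)
        assert np.allclose(c, y, atol=1e-3)
        found = np.flatnonzero(s > 0.5)
        assert set(found) == {40, 120, 200}

    def test_spikes_equal_difference_operator_applied_to_trace(self, rng):
        ar = ARModel(np.array([0.88]))
        y = np.abs(rng.standard_normal(200))
        c, s, b = deconvolve_trace(y, ar, 0.3)
        assert np.allclose(s, ar.spikes_from_trace(c), atol=1e-8)

    def test_denoised_closer_to_truth_than_raw(self, rng):
        from cnmfe.simulate import calcium_kernel

        T = 2000
        kernel = calcium_kernel(6.0, 1.0, T)
        wins = 0
        n = 20
        for i in range(n):
            spikes = (rng.random(T) < 0.01) * 1.0
            c_true = np.convolve(spikes, kernel)[:T]
            y = c_true + 0.05 * rng.standard_normal(T)
            sig = 0.05
            ar = fit_ar_coefficients(y, 2, sig)
            c, s, b = deconvolve_trace(y, ar, sig)
            if np.linalg.norm(c - c_true) <= np.linalg.norm(y - c_true):
                wins += 1
        assert wins >= 0.95 * n


class TestProjection:
    def test_zero_residual_returns_previous(self):
        a = np.array([1.0, 2.0, 0.0])
        c_prev = np.arange(5.0)
        out = project_residual_trace(np.zeros((3, 5)), a, c_prev)
        assert np.allclose(out, c_prev)

    def test_rank_one_residual_recovered_exactly(self, rng):
        a = np.abs(rng.random(10)) + 0.1
        delta = rng.standard_normal(30)
        out = project_residual_trace(np.outer(a, delta), a, np.zeros(30))
        assert np.allclose(out, delta, atol=1e-10)

    def test_noise_variance_matches_formula(self, rng):
        a = np.abs(rng.random(50)) + 0.1
        sig = 0.5 + rng.random(50)
        reps = 400
        var_emp = np.var([
            project_residual_trace(
                (sig[:, None] * rng.standard_normal((50, 1))), a, np.zeros(1))[0]
            for _ in range(reps)
        ])
        var_theory = float((a**2 * sig**2).sum() / (a @ a) ** 2)
        assert abs(var_emp - var_theory) < 0.3 * var_theory

    def test_zero_footprint_raises(self):
        with pytest.raises(ValueError):
            project_residual_trace(np.zeros((3, 5)), np.zeros(3), np.zeros(5))


class TestUpdateTemporal:
    def test_noiseless_single_component_exact(self):
        rng = np.random.default_rng(2)
        d, T = 36, 400
        a = np.zeros(d)
        a[10:14] = [0.5, 1.0, 0.8, 0.3]
        ar = ARModel(np.array([0.9]))
        h = ar.impulse_response(T)
        s_true = np.zeros(T)
        s_true[[50, 150, 300]] = [1.0, 2.0, 1.5]
        c_true = np.convolve(s_true, h)[:T]
        Y = np.outer(a, c_true).astype(np.float32)
        C0 = np.zeros((1, T))
        S0 = np.zeros((1, T))
        C, S, C_raw, b0, ars, kept = update_temporal(
            Y, a[:, None], C0, S0, np.zeros(d, dtype=np.float32),
            np.zeros((d, T), dtype=np.float32), [ar],
            sigma_traces=[1e-6], optimize_baseline=False)
        assert kept[0]
        assert np.allclose(C[0], c_true, atol=1e-6)

    def test_no_components_refreshes_baseline_only(self):
        Y = np.full((9, 50), 2.0, dtype=np.float32)
        Bf = np.zeros((9, 50), dtype=np.float32)
        C, S, C_raw, b0, ars, kept = update_temporal(
            Y, np.zeros((9, 0)), np.zeros((0, 50)), np.zeros((0, 50)),
            np.zeros(9, dtype=np.float32), Bf, [])
        assert np.allclose(b0, 2.0)


class TestOasisProperties:
    """Constraint and optimality invariants over arbitrary inputs."""

    from hypothesis import given, settings, strategies as st

    @given(
        y=st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                   min_size=2, max_size=40),
        gamma=st.floats(0.0, 0.98),
        lam=st.floats(0.0, 2.0),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_constraints_and_no_worse_than_trivial_solutions(self, y, gamma, lam):
        y = np.asarray(y, dtype=np.float64)
        c, s = oasis_ar1(y, gamma, lam=lam)
        assert np.all(c >= -1e-9)
        assert np.all(s >= -1e-9)
        assert np.allclose(s[1:], c[1:] - gamma * c[:-1], atol=1e-9)

        def obj(cc):
            ss = np.empty_like(cc)
            ss[0] = cc[0]
            ss[1:] = cc[1:] - gamma * cc[:-1]
            return 0.5 * ((cc - y) ** 2).sum() + lam * ss.sum()

        # optimal solution beats the all-zero feasible point
        assert obj(c) <= obj(np.zeros_like(y)) + 1e-9
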