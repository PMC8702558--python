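"""Core dynamics: connectivity statistics, local field, Euler integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tsnet
from tsnet.model import InputSchedule


class TestInitConnectivity:
    def test_jx_entries_and_zero_diagonal(self, params):
        conn = tsnet.init_connectivity(params, 0)
        off = ~np.eye(params.N, dtype=bool)
        assert np.all(np.diag(conn.JX) == 0.0)
        # off-diagonal magnitudes are forced by construction
        assert np.allclose(np.abs(conn.JX[off]), 1 / np.sqrt(params.N - 1))
        # both signs present in fair proportion
        frac_pos = np.mean(conn.JX[off] > 0)
        assert 0.45 < frac_pos < 0.55

    def test_jxy_sparsity_and_amplitude(self, params):
        conn = tsnet.init_connectivity(params, 1)
        nz = conn.JXY[conn.JXY != 0]
        # expected nonzero fraction 2*rho = 0.10, binomial sd ~ 0.003
        assert abs(nz.size / conn.JXY.size - 2 * params.rho) < 0.01
        assert np.allclose(np.abs(nz), params.c / np.sqrt(params.N))

    def test_reproducible_from_seed(self, params):
        a = tsnet.init_connectivity(params, 42)
        b = tsnet.init_connectivity(params, 42)
        assert np.array_equal(a.JX, b.JX) and np.array_equal(a.JXY, b.JXY)

    def test_invalid_rho_rejected(self):
        with pytest.raises(tsnet.ConfigError):
            tsnet.ModelParams(rho=0.6)

    def test_jxy_immutable(self, params):
        conn = tsnet.init_connectivity(params, 3)
        with pytest.raises(ValueError):
            conn.JXY[0, 0] = 1.0


class TestLocalField:
    def test_zero_state_zero_input_gives_zero(self, params):
        conn = tsnet.init_connectivity(params, 0)
        state = tsnet.NetworkState(np.zeros(params.N), np.zeros(params.N))
        lf = tsnet.compute_local_field(state, conn, np.zeros(params.N))
        assert np.allclose(lf.I, 0.0)

    def test_odd_symmetry(self, tiny_setup):
        params, conn, state, eta = tiny_setup
        lf = tsnet.compute_local_field(state, conn, eta)
        neg = tsnet.NetworkState(-state.x, -state.y)
        lf_neg = tsnet.compute_local_field(neg, conn, -eta)
        assert np.allclose(lf_neg.I, -lf.I, atol=1e-14)

    def test_hand_evaluated_three_unit_field(self):
        # scalar evaluation of I_i = sum_{j!=i} JX_ij x_j + tanh(r_i) + eta_i
        JX = np.array([[0.0, 0.2, -0.1], [0.5, 0.0, 0.3], [-0.4, 0.1, 0.0]])
        JXY = np.array([[0.0, 0.7, 0.0], [0.0, 0.0, -0.7], [0.7, 0.0, 0.0]])
        x = np.array([0.5, -0.25, 0.8])
        y = np.array([0.1, -0.6, 0.3])
        eta = np.array([1.0, -1.0, 1.0])
        conn = tsnet.Connectivity(JX, JXY)
        lf = tsnet.compute_local_field(tsnet.NetworkState(x, y), conn, eta)
        ty = np.tanh(y)
        expected = []
        for i in range(3):
            u_i = sum(JX[i, j] * x[j] for j in range(3) if j != i)
            r_i = sum(JXY[i, j] * ty[j] for j in range(3))
            expected.append(u_i + np.tanh(r_i) + eta[i])
        assert np.allclose(lf.I, expected, atol=1e-15)

    def test_dimension_mismatch(self, tiny_setup):
        params, conn, state, _ = tiny_setup
        with pytest.raises(tsnet.ConfigError):
            tsnet.compute_local_field(state, conn, np.zeros(4))


class TestStep:
    def test_fixed_point_is_stationary(self, tiny_setup):
        params, conn, state, eta = tiny_setup
        # construct a self-consistent state: iterate the map to convergence
        x = state.x.copy()
        y = state.y.copy()
        for _ in range(20000):
            lf = tsnet.compute_local_field(tsnet.NetworkState(x, y), conn, eta)
            x = np.tanh(params.beta_x * lf.I)
            y = np.tanh(params.beta_y * x)
        st0 = tsnet.NetworkState(x, y)
        st1 = tsnet.step(st0, conn, params, eta, dt=0.05)
        assert np.allclose(st1.x, x, atol=1e-9)
        assert np.allclose(st1.y, y, atol=1e-9)

    def test_large_tau_y_freezes_slow_state(self, tiny_setup):
        params, conn, state, eta = tiny_setup
        slow = tsnet.ModelParams(N=6, rho=0.25, tau_y=1e9)
        st1 = tsnet.step(state, conn, slow, eta, dt=0.05)
        assert np.max(np.abs(st1.y - state.y)) < 1e-9

    def test_step_too_coarse_rejected(self, tiny_setup):
        params, conn, state, eta = tiny_setup
        with pytest.raises(tsnet.ConfigError):
            tsnet.step(state, conn, params, eta, dt=0.2)

    def test_richardson_halved_step(self, tiny_setup):
        """One dt step vs two dt/2 steps agree to O(dt^2)."""
        params, conn, state, eta = tiny_setup
        dt = 0.05
        one = tsnet.step(state, conn, params, eta, dt=dt)
        half = tsnet.step(
            tsnet.step(state, conn, params, eta, dt=dt / 2), conn, params, eta, dt=dt / 2
        )
        assert np.max(np.abs(one.x - half.x)) < 5 * dt**2


class TestSimulate:
    def test_decay_with_zero_connectivity_and_input(self, params):
        conn = tsnet.Connectivity(
            np.zeros((params.N, params.N)), np.zeros((params.N, params.N))
        )
        x0 = np.full(params.N, 0.8)
        traj = tsnet.simulate(
            tsnet.NetworkState(x0, np.zeros(params.N)),
            conn,
            params,
            InputSchedule.zero(params.N),
            duration=5.0,
        )
        # x decays toward 0 with time constant tau_x = 1
        idx = np.argmin(np.abs(traj.times - 1.0))
        assert abs(traj.X[idx, 0] - 0.8 * np.exp(-1.0)) < 0.03
        assert abs(traj.X[-1, 0]) < 0.01 * 0.8 + 0.01

    def test_deterministic_rerun_identical(self, tiny_setup):
        params6, conn, state, eta = tiny_setup
        kw = dict(duration=20.0, dt=0.05)
        a = tsnet.simulate(state, conn, params6, InputSchedule.constant(eta), **kw)
        b = tsnet.simulate(state, conn, params6, InputSchedule.constant(eta), **kw)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.Y, b.Y)

    def test_noisy_run_reproducible_from_seed(self, tiny_setup):
        params6, conn, state, eta = tiny_setup
        noise = tsnet.NoiseConfig(s=0.2)
        runs = [
            tsnet.simulate(
                state, conn, params6, InputSchedule.constant(eta), 10.0,
                noise=noise, rng=np.random.default_rng(5),
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].X, runs[1].X)

    def test_odd_symmetry_of_trajectories(self, tiny_setup):
        params6, conn, state, eta = tiny_setup
        a = tsnet.simulate(state, conn, params6, InputSchedule.constant(eta), 30.0)
        neg = tsnet.NetworkState(-state.x, -state.y)
        b = tsnet.simulate(neg, conn, params6, InputSchedule.constant(-eta), 30.0)
        assert np.allclose(a.X, -b.X, atol=1e-12)
        assert np.allclose(a.Y, -b.Y, atol=1e-12)

    def test_boundedness(self, tiny_setup):
        params6, conn, state, eta = tiny_setup
        traj = tsnet.simulate(state, conn, params6, InputSchedule.constant(eta), 100.0)
        assert np.max(np.abs(traj.X)) <= 1.0
        assert np.max(np.abs(traj.Y)) <= 1.0

    def test_euler_error_decreases_monotonically(self, tiny_setup):
        """Global Euler error shrinks as dt is halved (first-order scheme)."""
        params6, conn, state, eta = tiny_setup
        sched = InputSchedule.constant(eta)

        def endpoint(dt):
            traj = tsnet.simulate(state, conn, params6, sched, 10.0, dt=dt)
            return traj.X[-1]

        ref = endpoint(0.003125)
        errs = [np.max(np.abs(endpoint(dt) - ref)) for dt in (0.1, 0.05, 0.025)]
        assert errs[0] > errs[1] > errs[2]

    def test_quenched_slow_limit(self, tiny_setup):
        """With tau_y >= 1e6 the slow state drifts < 1e-3 over 100 units."""
        _, conn, state, eta = tiny_setup
        frozen = tsnet.ModelParams(N=6, rho=0.25, tau_y=1e6)
        traj = tsnet.simulate(state, conn, frozen, InputSchedule.constant(eta), 100.0)
        assert np.max(np.abs(traj.Y - traj.Y[0])) < 1e-3

    def test_empty_schedule_rejected(self):
        with pytest.raises(tsnet.ConfigError):
            InputSchedule([])


class TestOverlap:
    def test_perfect_and_anti_overlap(self):
        xi = np.array([1.0, -1.0, 1.0, 1.0])
        assert tsnet.overlap(xi, xi) == 1.0
        assert tsnet.overlap(-xi, xi) == -1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_dot_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-1, 1, 100)
        xi = 2.0 * rng.integers(0, 2, 100) - 1.0
        brute = sum(v[i] * xi[i] for i in range(100)) / 100
        assert abs(tsnet.overlap(v, xi) - brute) < 1e-12
        assert -1.0 <= tsnet.overlap(v, xi) <= 1.0


class TestIO:
    def test_trajectory_roundtrip(self, tmp_path, tiny_setup):
        params6, conn, state, eta = tiny_setup
        traj = tsnet.simulate(state, conn, params6, InputSchedule.constant(eta), 10.0)
        path = tmp_path / "traj.h5"
        tsnet.save_trajectory(path, traj)
        loaded = tsnet.load_trajectory(path)
        assert np.array_equal(loaded.X, traj.X)
        assert np.array_equal(loaded.times, traj.times)
        assert loaded.sample_rate == traj.sample_rate
        assert loaded.meta == traj.meta

    def test_connectivity_roundtrip(self, tmp_path, params):
        conn = tsnet.init_connectivity(params, 9)
        path = tmp_path / "conn.h5"
        tsnet.save_connectivity(path, conn, params, seed=9)
        loaded, p2 = tsnet.load_connectivity(path)
        assert np.array_equal(loaded.JX, conn.JX)
        assert np.array_equal(loaded.JXY, conn.JXY)
        assert p2 == params
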