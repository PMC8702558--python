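"""Learning rule and training procedure."""

import numpy as np
import pytest

import tsnet
from tsnet.plasticity import LearningCriteria, plasticity_update


class TestPlasticityUpdate:
    def test_frozen_at_target(self, tiny_setup):
        params, conn, state, _ = tiny_setup
        xi = np.sign(np.where(state.x == 0, 1.0, state.x))
        state.x = xi.copy()
        before = conn.JX.copy()
        plasticity_update(conn, state, xi, params, dt=0.05)
        assert np.array_equal(conn.JX, before)

    def test_two_unit_hand_computation(self):
        # scalar evaluation of dJ_ij = (dt/tau_syn)(1/N)(xi_i - x_i)(x_j - u_i J_ij)
        params = tsnet.ModelParams(N=2, tau_syn=50.0)
        JX = np.array([[0.0, 0.4], [-0.3, 0.0]])
        conn = tsnet.Connectivity(JX.copy(), np.zeros((2, 2)))
        x = np.array([0.2, -0.6])
        xi = np.array([1.0, -1.0])
        dt = 0.1
        u = [JX[0, 1] * x[1], JX[1, 0] * x[0]]
        expect_01 = JX[0, 1] + dt / 50.0 * 0.5 * (xi[0] - x[0]) * (x[1] - u[0] * JX[0, 1])
        expect_10 = JX[1, 0] + dt / 50.0 * 0.5 * (xi[1] - x[1]) * (x[0] - u[1] * JX[1, 0])
        plasticity_update(conn, tsnet.NetworkState(x, np.zeros(2)), xi, params, dt)
        assert conn.JX[0, 1] == pytest.approx(expect_01, abs=1e-15)
        assert conn.JX[1, 0] == pytest.approx(expect_10, abs=1e-15)
        assert conn.JX[0, 0] == conn.JX[1, 1] == 0.0

    def test_diagonal_stays_zero_under_updates(self, tiny_setup):
        params, conn, state, _ = tiny_setup
        rng = np.random.default_rng(0)
        for _ in range(50):
            state.x = rng.uniform(-1, 1, params.N)
            xi = 2.0 * rng.integers(0, 2, params.N) - 1.0
            plasticity_update(conn, state, xi, params, dt=0.05)
        assert np.all(np.diag(conn.JX) == 0.0)

    def test_locality(self, tiny_setup):
        """dJ_ij is computable from (xi_i, x_i, u_i, J_ij, x_j) alone."""
        params, conn, state, _ = tiny_setup
        rng = np.random.default_rng(1)
        state.x = rng.uniform(-1, 1, params.N)
        xi = 2.0 * rng.integers(0, 2, params.N) - 1.0
        u = conn.JX @ state.x
        J0 = conn.JX.copy()
        dt = 0.05
        local = np.zeros_like(J0)
        for i in range(params.N):
            for j in range(params.N):
                if i != j:
                    local[i, j] = (
                        dt / (params.tau_syn * params.N)
                        * (xi[i] - state.x[i])
                        * (state.x[j] - u[i] * J0[i, j])
                    )
        plasticity_update(conn, state, xi, params, dt)
        assert np.allclose(conn.JX - J0, local, atol=1e-15)

    def test_kernel_matches_reference_update(self, tiny_setup):
        """The compiled training kernel applies the same J update as the
        pure-python rule for one Euler step."""
        from tsnet._kernels import present_pattern

        params, conn, state, eta = tiny_setup
        xi = 2.0 * np.random.default_rng(3).integers(0, 2, params.N) - 1.0
        ref = conn.copy()
        plasticity_update(ref, state, xi, params, dt=0.05)
        x, y = state.x.copy(), state.y.copy()
        present_pattern(
            conn.JX, conn.JXY, eta, xi, x, y, 0.05,
            params.tau_x, params.tau_y, params.tau_syn,
            params.beta_x, params.beta_y, 0.85, 0.5, 1, False, True,
        )
        assert np.allclose(conn.JX, ref.JX, atol=1e-14)


class TestSwitchPerturbation:
    def test_zero_maps_to_zero(self):
        assert np.all(tsnet.apply_switch_perturbation(np.zeros(10), 0) == 0.0)

    def test_shrinks_and_preserves_sign(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, 1000)
        out = tsnet.apply_switch_perturbation(x, rng)
        assert np.all(np.abs(out) <= np.abs(x))
        assert np.all(np.sign(out[out != 0]) == np.sign(x[out != 0]))

    def test_mean_shrink_factor_is_half(self):
        rng = np.random.default_rng(5)
        x = np.ones(200_000)
        out = tsnet.apply_switch_perturbation(x, rng)
        assert abs(out.mean() - 0.5) < 0.005  # U[0,1] mean, MC error ~6e-4


class TestTrainPattern:
    def test_immediate_return_when_converged(self, params):
        rng = np.random.default_rng(6)
        conn = tsnet.init_connectivity(params, rng)
        xi = 2.0 * rng.integers(0, 2, params.N) - 1.0
        state = tsnet.NetworkState(xi * 0.99, xi * 0.95)
        rec = tsnet.train_pattern(conn, state, xi, xi, params)
        assert rec.converged
        assert rec.time_to_criterion <= 0.05 + 1e-12

    def test_single_pattern_converges_from_fresh_network(self, params):
        """A fresh net learns one input->target map well within the cap."""
        rng = np.random.default_rng(7)
        conn = tsnet.init_connectivity(params, rng)
        xi = 2.0 * rng.integers(0, 2, params.N) - 1.0
        eta = 2.0 * rng.integers(0, 2, params.N) - 1.0
        state = tsnet.NetworkState(rng.uniform(-1, 1, params.N), np.zeros(params.N))
        rec = tsnet.train_pattern(conn, state, xi, eta, params)
        assert rec.converged
        assert rec.final_mx > 0.85 and rec.final_mxy > 0.5
        assert rec.time_to_criterion < 1000.0


class TestTrainSequences:
    def test_zero_epochs_leaves_connectivity_unchanged(self, params):
        rng = np.random.default_rng(8)
        task = tsnet.make_simple_task(params.N, 1, 3, rng)
        conn = tsnet.init_connectivity(params, rng)
        before = conn.JX.copy()
        net = tsnet.train_sequences(conn, task, params, epochs=0, rng=rng)
        assert np.array_equal(net.conn.JX, before)
        assert not net.log.records

    def test_reproducible_log_and_connectivity(self, params):
        def run():
            rng = np.random.default_rng(99)
            task = tsnet.make_simple_task(params.N, 1, 2, rng)
            conn = tsnet.init_connectivity(params, rng)
            return tsnet.train_sequences(conn, task, params, epochs=2, rng=rng)

        a, b = run(), run()
        assert np.array_equal(a.conn.JX, b.conn.JX)
        assert a.log.to_dataframe().equals(b.log.to_dataframe())

    def test_connectivity_stays_bounded(self, trained_k1m3):
        net, _, _ = trained_k1m3
        assert np.all(np.isfinite(net.conn.JX))
        assert np.max(np.abs(net.conn.JX)) < 5.0
        assert np.all(np.diag(net.conn.JX) == 0.0)

    def test_log_structure(self, trained_k1m3):
        net, task, _ = trained_k1m3
        df = net.log.to_dataframe()
        assert len(df) == 20 * 3
        assert df.epoch.max() == 19
        assert set(df.label) == set(task.expected(0))
        assert (df.time_to_criterion <= 1000.0).all()

    def test_stored_slow_states_shape(self, trained_k1m3):
        net, task, _ = trained_k1m3
        assert net.y_seq_init.shape == (task.K, net.params.N)
        assert np.array_equal(net.y_seq_init[0], net.y_final)


class TestTrainTimed:
    def test_zero_present_time_is_noop(self, params):
        rng = np.random.default_rng(10)
        task = tsnet.make_inference_task(params.N, rng)
        conn = tsnet.init_connectivity(params, rng)
        before = conn.JX.copy()
        net = tsnet.train_timed(conn, task.phase1, params, present_time=0.0, rng=rng)
        assert np.array_equal(net.conn.JX, before)

    def test_total_training_time_bookkeeping(self, params):
        rng = np.random.default_rng(11)
        task = tsnet.make_inference_task(params.N, rng)
        conn = tsnet.init_connectivity(params, rng)
        epochs = 2
        net = tsnet.train_timed(conn, task.phase1, params, 100.0, epochs, rng=rng)
        n_presentations = sum(s.M for s in task.phase1.sequences)
        assert net.log.total_time == pytest.approx(epochs * n_presentations * 100.0)
        assert all(
            r.time_to_criterion == pytest.approx(100.0) for r in net.log.records
        )


class TestCriteriaValidation:
    def test_thresholds_must_be_interior(self):
        with pytest.raises(tsnet.ConfigError):
            LearningCriteria(target_overlap=1.5)
        with pytest.raises(tsnet.ConfigError):
            LearningCriteria(xy_overlap=0.0)


class TestPersistence:
    def test_network_roundtrip(self, tmp_path, trained_k1m3):
        net, task, _ = trained_k1m3
        path = tmp_path / "net.h5"
        tsnet.save_network(path, net)
        loaded = tsnet.load_network(path)
        assert np.array_equal(loaded.conn.JX, net.conn.JX)
        assert np.array_equal(loaded.y_seq_init, net.y_seq_init)
        assert loaded.task.to_json() == task.to_json()
        assert loaded.params == net.params
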