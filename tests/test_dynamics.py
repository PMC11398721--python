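"""Simulator: order parameters, derivatives, Euler integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tesnet as tn
from tesnet.dynamics import derivatives, global_order, init_state, local_order


def star_graph(n_leaves):
    """Node 0 receives from all leaves (undirected star)."""
    n = n_leaves + 1
    w = np.zeros((n, n))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return tn.NetworkGraph(w)


class TestParams:
    def test_mode_exclusivity(self):
        with pytest.raises(ValueError):
            tn.ModelParams(lambda_o=0.1, fixed_lambda=0.1)
        with pytest.raises(ValueError):
            tn.ModelParams()
        assert tn.ModelParams(lambda_o=0.1).mode == "resource"
        assert tn.ModelParams(fixed_lambda=0.1).mode == "fixed"

    def test_with_switches_mode(self):
        p = tn.ModelParams(lambda_o=0.1)
        q = p.with_(fixed_lambda=0.5)
        assert q.mode == "fixed" and q.lambda_o is None

    def test_positivity_checks(self):
        with pytest.raises(ValueError):
            tn.ModelParams(lambda_o=0.1, dt=0.0)
        with pytest.raises(ValueError):
            tn.ModelParams(lambda_o=-0.1)


class TestInitState:
    def test_determinism(self, connectome):
        p = tn.ModelParams(lambda_o=0.3, seed=42)
        a, b = init_state(connectome, p), init_state(connectome, p)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.omega, b.omega)

    def test_frequency_mean_near_zero(self):
        g = tn.NetworkGraph(np.zeros((10_000, 10_000)))
        s = init_state(g, tn.ModelParams(lambda_o=0.1, seed=7))
        se = (2 / np.sqrt(12)) / np.sqrt(10_000)  # sd of U(-1,1) / sqrt(n)
        assert abs(s.omega.mean()) < 3 * se
        assert s.theta.min() >= 0.0 and s.theta.max() < 2 * np.pi

    def test_fixed_mode_initial_resources(self, connectome):
        s = init_state(connectome, tn.ModelParams(fixed_lambda=0.1))
        assert np.all(s.lam == 0.1)


class TestLocalOrder:
    def test_identical_neighbor_phases(self):
        g = star_graph(4)
        theta = np.array([1.0, 0.3, 0.3, 0.3, 0.3])
        assert local_order(theta, g)[0] == pytest.approx(1.0)

    def test_antiphase_cancellation(self):
        g = star_graph(2)
        theta = np.array([0.5, 0.0, np.pi])
        assert local_order(theta, g)[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_neighbor_hand_value(self):
        g = star_graph(3)
        theta = np.array([0.0, 0.0, np.pi / 2, np.pi])
        # |1 + i - 1| / 3 = 1/3
        assert local_order(theta, g)[0] == pytest.approx(1 / 3)

    def test_isolated_node_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = tn.NetworkGraph(w)
        assert local_order(np.array([0.0, 0.0, 0.0]), g)[2] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        np.fill_diagonal(w, 0.0)
        g = tn.NetworkGraph(w / max(w.max(), 1e-9), directed=True,
                            weighted=True)
        r = local_order(rng.uniform(0, 2 * np.pi, n), g)
        assert np.all(r >= 0.0) and np.all(r <= 1.0)


class TestGlobalOrder:
    @pytest.mark.parametrize("theta,expected", [
        (np.full(5, 1.3), 1.0),
        (np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3]), 0.0),
        (np.array([0.0, np.pi / 2]), np.sqrt(2) / 2),
    ])
    def test_hand_values(self, theta, expected):
        assert global_order(theta) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_order(np.array([]))


def oracle_derivatives(state, g, p):
    """Literal nested-loop evaluation of the model equations."""
    n = g.n_nodes
    w = g.weights
    dth = np.zeros(n)
    dlam = np.zeros(n)
    for i in range(n):
        s_in = sum(w[i, j] for j in range(n))
        if s_in > 0:
            z = sum(w[i, j] * np.exp(1j * state.theta[j]) for j in range(n))
            r_i = abs(z) / s_in
        else:
            r_i = 0.0
        coupling = sum(w[i, j] * np.sin(state.theta[j] - state.theta[i])
                       for j in range(n))
        lam_i = p.fixed_lambda if p.mode == "fixed" else state.lam[i]
        dth[i] = state.omega[i] + lam_i * r_i * coupling
        if p.mode == "resource":
            dlam[i] = p.alpha * (p.lambda_o - state.lam[i]) - p.beta * r_i
    return dth, dlam


class TestDerivatives:
    @pytest.mark.parametrize("mode_kw", [{"lambda_o": 0.4},
                                         {"fixed_lambda": 0.7}])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, mode_kw, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        w = (rng.random((n, n)) < 0.5) * rng.random((n, n))
        np.fill_diagonal(w, 0.0)
        g = tn.NetworkGraph(w / max(w.max(), 1e-9), directed=True,
                            weighted=True)
        p = tn.ModelParams(seed=seed, **mode_kw)
        s = init_state(g, p)
        dth, dlam = derivatives(s, g, p)
        oth, olam = oracle_derivatives(s, g, p)
        np.testing.assert_allclose(dth, oth, atol=1e-12)
        np.testing.assert_allclose(dlam, olam, atol=1e-15)

    def test_isolated_node_drifts_at_natural_frequency(self):
        g = tn.NetworkGraph(np.zeros((2, 2)))
        p = tn.ModelParams(lambda_o=0.3)
        s = tn.OscillatorState(np.array([0.1, 0.2]), np.array([0.5, -0.5]),
                               np.array([0.3, 0.3]))
        dth, dlam = derivatives(s, g, p)
        np.testing.assert_array_equal(dth, s.omega)
        np.testing.assert_array_equal(dlam, np.zeros(2))  # lam at bath, r=0

    def test_full_synchrony_consumes_at_beta(self):
        g = tn.NetworkGraph(np.ones((3, 3)) - np.eye(3))
        p = tn.ModelParams(lambda_o=0.2, beta=0.002)
        s = tn.OscillatorState(np.zeros(3), np.zeros(3), np.full(3, 0.2))
        _, dlam = derivatives(s, g, p)  # r = 1, lam = lambda_o
        np.testing.assert_allclose(dlam, -0.002)

    def test_two_node_hand_evaluation(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = tn.NetworkGraph(w)
        p = tn.ModelParams(fixed_lambda=1.0)
        s = tn.OscillatorState(np.array([0.0, np.pi / 2]),
                               np.array([0.3, -0.2]), np.ones(2))
        dth, _ = derivatives(s, g, p)
        assert dth[0] == pytest.approx(0.3 + np.sin(np.pi / 2))


class TestSimulate:
    def test_kernel_single_step_matches_derivatives(self, connectome):
        p = tn.ModelParams(lambda_o=2.0, seed=5)
        s0 = init_state(connectome, p)
        traj = tn.simulate(connectome, p, duration=p.dt,
                           record_stride=p.dt, record_per_node=True,
                           state=s0)
        dth, dlam = derivatives(s0, connectome, p)
        expect_theta = (s0.theta + p.dt * dth) % (2 * np.pi)
        np.testing.assert_allclose(traj.theta_panel[1], expect_theta,
                                   atol=1e-12)
        np.testing.assert_allclose(traj.lam_panel[1], s0.lam + p.dt * dlam,
                                   atol=1e-15)

    def test_seeded_determinism_bit_identical(self, connectome):
        p = tn.ModelParams(lambda_o=2.2, seed=9)
        a = tn.simulate(connectome, p, 50.0)
        b = tn.simulate(connectome, p, 50.0)
        assert np.array_equal(a.R, b.R)
        assert np.array_equal(a.mean_lambda, b.mean_lambda)

    def test_order_parameter_bounds(self, connectome):
        p = tn.ModelParams(lambda_o=2.2, seed=1)
        traj = tn.simulate(connectome, p, 100.0, record_per_node=True)
        assert np.all((traj.R >= 0) & (traj.R <= 1))
        assert np.all((traj.r_panel >= 0) & (traj.r_panel <= 1))

    def test_resource_upper_bound(self, connectome):
        p = tn.ModelParams(lambda_o=1.5, seed=2)
        traj = tn.simulate(connectome, p, 200.0, record_per_node=True)
        assert np.all(traj.lam_panel <= 1.5 + 1e-12)

    def test_quiescent_relaxation_closed_form(self):
        # no edges -> r = 0 -> lambda relaxes exponentially toward the bath
        g = tn.NetworkGraph(np.zeros((4, 4)))
        p = tn.ModelParams(lambda_o=0.5, alpha=0.01, dt=0.05, seed=0)
        s = init_state(g, p)
        s.lam[:] = 0.1
        traj = tn.simulate(g, p, 5.0, record_stride=0.05, state=s)
        t = traj.times
        exact = 0.5 + (0.1 - 0.5) * np.exp(-p.alpha * t)
        # explicit Euler tracks the exact relaxation to O(dt)
        assert np.max(np.abs(traj.mean_lambda - exact)) < p.dt * p.alpha

    def test_no_coupling_keeps_bath_level_exact(self):
        g = tn.NetworkGraph(np.zeros((4, 4)))
        p = tn.ModelParams(lambda_o=0.3, seed=0)
        traj = tn.simulate(g, p, 20.0)
        assert np.all(traj.mean_lambda == 0.3)

    def test_zero_resource_stays_incoherent(self, swn400):
        p = tn.ModelParams(fixed_lambda=0.0, seed=0)
        traj = tn.simulate(swn400, p, 100.0)
        assert traj.R.mean() <= 3 / np.sqrt(400)

    def test_stride_validation(self, connectome):
        p = tn.ModelParams(lambda_o=0.1)
        with pytest.raises(ValueError):
            tn.simulate(connectome, p, 10.0, record_stride=0.07)
        with pytest.raises(ValueError):
            tn.simulate(connectome, p, -1.0)

    def test_nonfinite_state_raises_with_step(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = tn.NetworkGraph(w)
        p = tn.ModelParams(fixed_lambda=0.5, dt=0.05)
        bad = tn.OscillatorState(np.array([np.nan, 0.0]), np.zeros(2),
                                 np.full(2, 0.5))
        with pytest.raises(FloatingPointError, match="step 0"):
            tn.simulate(g, p, 5.0, state=bad)

    def test_trajectory_round_trip(self, tmp_path, connectome):
        p = tn.ModelParams(lambda_o=2.2, seed=3)
        traj = tn.simulate(connectome, p, 10.0, record_per_node=True)
        traj.save(tmp_path / "run")
        back = tn.Trajectory.load(tmp_path / "run")
        np.testing.assert_array_equal(back.R, traj.R)
        np.testing.assert_array_equal(back.theta_panel, traj.theta_panel)
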