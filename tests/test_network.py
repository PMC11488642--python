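"""Core dynamics: scores, softmax activities, drift, potential, Jacobian,
reciprocity and the physical-enhancer -> enhancer-type reduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancernet.network import (RegulatoryNetwork, check_reciprocity,
                                 drift, enhancer_activities,
                                 enhancer_scores, jacobian, potential,
                                 reduce_to_types)
from enhancernet.dynamics import simulate

from conftest import make_random_symmetric_net


def scalar_loop_scores(net, x):
    """Independent elementwise oracle for the score vector (no matrix ops)."""
    out = []
    for i in range(net.n_enhancers):
        s = 0.0
        for j in range(net.n_tfs):
            s += net.binding[i, j] * x[j]
        out.append(net.beta * net.gain[i] * s + net.weights[i])
    return np.array(out)


class TestScoresAndActivities:
    def test_zero_beta_zero_weights_give_zero_scores(self, rng):
        net = make_random_symmetric_net(rng, beta=0.0)
        x = rng.uniform(0, 1, net.n_tfs)
        assert np.all(enhancer_scores(net, x) == 0.0)

    def test_zero_state_returns_weights_exactly(self, rng):
        net = make_random_symmetric_net(rng, with_weights=True)
        assert np.array_equal(enhancer_scores(net, np.zeros(net.n_tfs)),
                              net.weights)

    def test_scores_match_scalar_loop_oracle(self, rng):
        net = make_random_symmetric_net(rng, n_enhancers=3, n_tfs=2,
                                        beta=2.7, with_weights=True)
        x = rng.uniform(0, 1, 2)
        assert enhancer_scores(net, x) == pytest.approx(
            scalar_loop_scores(net, x), abs=1e-12)

    def test_equal_scores_give_uniform_activities(self):
        xi = np.ones((4, 3))
        net = RegulatoryNetwork(("a", "b", "c"), ("e1", "e2", "e3", "e4"),
                                xi, xi, np.zeros(4), beta=3.0)
        p = enhancer_activities(net, np.array([1.0, 2.0, 0.5]))
        assert p == pytest.approx(np.full(4, 0.25), abs=1e-12)

    def test_log3_score_gap_gives_three_to_one_odds(self):
        xi = np.array([[0.0], [1.0]])
        net = RegulatoryNetwork(("t",), ("lo", "hi"), xi, xi,
                                np.zeros(2), beta=np.log(3.0))
        p = enhancer_activities(net, np.array([1.0]))
        assert p == pytest.approx([0.25, 0.75], abs=1e-12)

    def test_high_beta_concentrates_on_matching_pattern(self, rng):
        net = make_random_symmetric_net(rng, unit_norm=True, beta=200.0)
        for k in range(net.n_enhancers):
            p = enhancer_activities(net, net.binding[k])
            assert p[k] > 0.999

    def test_dimension_mismatch_names_tf_axis(self, random_symmetric_net):
        with pytest.raises(ValueError, match="TF axis"):
            enhancer_scores(random_symmetric_net, np.ones(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), beta=st.floats(0.0, 50.0))
    def test_activities_are_a_probability_vector(self, seed, beta):
        r = np.random.default_rng(seed)
        net = make_random_symmetric_net(r, beta=beta, with_weights=True)
        p = enhancer_activities(net, r.uniform(0, 2, net.n_tfs))
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


class TestDrift:
    def test_row_average_is_fixed_point_at_zero_beta(self, rng):
        net = make_random_symmetric_net(rng, beta=0.0)
        x = net.coupling.mean(axis=0)
        assert np.linalg.norm(drift(net, x)) < 1e-12

    def test_unit_patterns_are_fixed_points_at_high_beta(self, rng):
        net = make_random_symmetric_net(rng, unit_norm=True, beta=200.0)
        for row in net.binding:
            assert np.linalg.norm(drift(net, row)) < 1e-3

    def test_drift_is_negative_potential_gradient(self, rng):
        net = make_random_symmetric_net(rng, beta=4.0, with_weights=True)
        x = rng.uniform(0.2, 1.0, net.n_tfs)
        h = 1e-6
        grad = np.zeros_like(x)
        for j in range(x.size):
            e = np.zeros_like(x)
            e[j] = h
            grad[j] = (potential(net, x + e) - potential(net, x - e)) / (2*h)
        v = drift(net, x)
        assert v == pytest.approx(-grad / net.tau, rel=1e-5, abs=1e-8)


class TestPotential:
    def test_single_enhancer_minimum_at_its_pattern(self):
        xi = np.array([[0.6, 0.8]])
        net = RegulatoryNetwork(("a", "b"), ("e",), xi, xi, np.zeros(1),
                                beta=5.0)
        from scipy.optimize import minimize
        res = minimize(lambda x: potential(net, np.clip(x, 0, None)),
                       x0=np.array([0.2, 0.2]))
        assert np.clip(res.x, 0, None) == pytest.approx(xi[0], abs=1e-5)

    def test_potential_non_increasing_along_trajectory(self, rng):
        net = make_random_symmetric_net(rng, beta=6.0, with_weights=True)
        x0 = rng.uniform(0, 1.2, net.n_tfs)
        traj = simulate(net, x0, (0.0, 20.0))
        V = np.array([potential(net, x) for x in traj.states])
        assert np.all(np.diff(V) <= 1e-8)

    def test_potential_difference_equals_line_integral_of_drift(self, rng):
        net = make_random_symmetric_net(rng, beta=3.0)
        a = rng.uniform(0.1, 1.0, net.n_tfs)
        b = rng.uniform(0.1, 1.0, net.n_tfs)
        ts = np.linspace(0.0, 1.0, 2001)
        integrand = np.array(
            [-net.tau * drift(net, a + t * (b - a)) @ (b - a) for t in ts])
        quad = np.trapezoid(integrand, ts)
        assert potential(net, b) - potential(net, a) == pytest.approx(
            quad, abs=1e-4)

    def test_beta_zero_limit_is_mean_field(self, rng):
        net = make_random_symmetric_net(rng, beta=0.0, with_weights=True)
        x = rng.uniform(0, 1, net.n_tfs)
        from scipy.special import softmax
        expected = 0.5 * x @ x - softmax(net.weights) @ (net.binding @ x)
        assert potential(net, x) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_network_has_no_potential(self, rng):
        xi = rng.uniform(0, 1, (3, 4))
        q = xi.copy()
        q[0, 0] += 0.5
        net = RegulatoryNetwork(tuple("abcd"), tuple("xyz"), xi, q,
                                np.zeros(3), beta=2.0)
        with pytest.raises(ValueError, match="asymmetric"):
            potential(net, np.ones(4))


class TestJacobian:
    def test_zero_beta_jacobian_is_pure_decay(self, rng):
        net = make_random_symmetric_net(rng, beta=0.0)
        J = jacobian(net, rng.uniform(0, 1, net.n_tfs))
        assert J == pytest.approx(-np.eye(net.n_tfs) / net.tau, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_jacobian_matches_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        xi = r.uniform(0, 1, (4, 5))
        q = r.uniform(0, 1, (4, 5))  # general asymmetric net
        net = RegulatoryNetwork(tuple("abcde"), tuple("wxyz"), xi, q,
                                r.normal(0, 0.2, 4), beta=3.0)
        x = r.uniform(0.1, 1.0, 5)
        J = jacobian(net, x)
        h = 1e-6
        for j in range(5):
            e = np.zeros(5)
            e[j] = h
            col = (drift(net, x + e) - drift(net, x - e)) / (2 * h)
            assert J[:, j] == pytest.approx(col, rel=1e-5, abs=1e-7)

    def test_symmetric_net_has_symmetric_jacobian(self, rng):
        net = make_random_symmetric_net(rng, beta=7.0, with_weights=True)
        for _ in range(5):
            J = jacobian(net, rng.uniform(0, 1.5, net.n_tfs))
            assert np.max(np.abs(J - J.T)) < 1e-9


class TestReciprocity:
    def test_equal_matrices_are_reciprocal(self, random_symmetric_net):
        rep = check_reciprocity(random_symmetric_net)
        assert rep.is_reciprocal
        assert rep.nu == pytest.approx(1.0)
        assert random_symmetric_net.symmetric

    def test_scaled_coupling_is_reciprocal_with_fitted_nu(self, rng):
        xi = rng.uniform(0, 1, (3, 5))
        net = RegulatoryNetwork(tuple("abcde"), tuple("xyz"), xi, 2.0 * xi,
                                np.zeros(3), beta=4.0)
        rep = check_reciprocity(net)
        assert rep.is_reciprocal
        assert rep.nu == pytest.approx(2.0)
        assert net.symmetric

    def test_single_perturbed_entry_breaks_reciprocity(self, rng):
        xi = rng.uniform(0.1, 1, (3, 5))
        q = xi.copy()
        q[1, 2] += 0.5
        net = RegulatoryNetwork(tuple("abcde"), tuple("xyz"), xi, q,
                                np.zeros(3), beta=4.0)
        rep = check_reciprocity(net)
        assert not rep.is_reciprocal
        assert not net.symmetric
        assert rep.is_reciprocal == net.symmetric


class TestReduceToTypes:
    def test_distinct_rows_pass_through(self, rng):
        net = make_random_symmetric_net(rng)
        red = reduce_to_types(net)
        assert red.enhancer_names == net.enhancer_names
        assert np.array_equal(red.binding, net.binding)

    def test_two_identical_rows_merge_with_log2_weight(self):
        xi = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        q = np.array([[0.8, 0.0], [0.4, 0.2], [0.0, 1.0]])
        net = RegulatoryNetwork(("a", "b"), ("e1", "e2", "e3"), xi, q,
                                np.zeros(3), beta=2.0)
        red = reduce_to_types(net)
        assert red.n_enhancers == 2
        assert red.weights[0] == pytest.approx(np.log(2.0))
        assert red.coupling[0] == pytest.approx([0.6, 0.1])

    @pytest.mark.parametrize("seed", range(3))
    def test_reduction_preserves_trajectories(self, seed):
        r = np.random.default_rng(seed)
        base = r.uniform(0, 1, (3, 6))
        xi = np.vstack([base, base[[0, 2, 1]]])  # 3 duplicated rows
        q = r.uniform(0, 1, (6, 6))
        net = RegulatoryNetwork(tuple(f"t{i}" for i in range(6)),
                                tuple(f"e{i}" for i in range(6)),
                                xi, q, r.normal(0, 0.5, 6), beta=3.0)
        red = reduce_to_types(net)
        assert red.n_enhancers == 3
        for _ in range(4):
            x0 = r.uniform(0, 1, 6)
            a = simulate(net, x0, (0.0, 10.0)).final_state
            b = simulate(red, x0, (0.0, 10.0)).final_state
            assert a == pytest.approx(b, abs=1e-6)

    def test_reduction_is_idempotent(self, rng):
        xi = np.vstack([np.ones((2, 3)), rng.uniform(0, 1, (1, 3))])
        net = RegulatoryNetwork(("a", "b", "c"), ("e1", "e2", "e3"),
                                xi, rng.uniform(0, 1, (3, 3)),
                                np.zeros(3), beta=2.0)
        once = reduce_to_types(net)
        twice = reduce_to_types(once)
        assert once.enhancer_names == twice.enhancer_names
        assert np.array_equal(once.coupling, twice.coupling)


class TestNetworkValidation:
    def test_negative_binding_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            RegulatoryNetwork(("a",), ("e",), np.array([[-1.0]]),
                              np.array([[1.0]]), np.zeros(1))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RegulatoryNetwork(("a", "b"), ("e",), np.ones((1, 2)),
                              np.ones((2, 2)), np.zeros(1))

    def test_symmetry_flag_is_recomputed_not_asserted(self, rng):
        xi = rng.uniform(0.1, 1, (2, 3))
        net = RegulatoryNetwork(("a", "b", "c"), ("x", "y"), xi,
                                3.0 * xi, np.zeros(2))
        assert net.symmetric and net.nu == pytest.approx(3.0)
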