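"""The relative-entropy IRL core: dual, gradients, baselines and the fit loop."""

import datetime as dt
import math

import numpy as np
import pytest

import residentirl as ri
from residentirl.features import N_FEATURES
from residentirl.gridworld import Action, State, build_mdp, estimate_transitions
from residentirl.relent_irl import (
    BaselinePolicy,
    IrlConfig,
    RoutineBaseline,
    TrajectoryFeatures,
    baseline_logprob,
    bernstein_epsilon,
    dual_gradient,
    dual_value,
    fit,
    hoeffding_epsilon,
    rollout_baseline,
    trajectory_prob,
    trajectory_reward,
)
from residentirl.trajectories import Trajectory


def _random_instance(rng, n=12, k=N_FEATURES):
    Phi = rng.uniform(0, 1, size=(n, k))
    log_q = rng.normal(-5, 1, size=n)
    mu = Phi.mean(axis=0) + rng.normal(0, 0.05, size=k)
    eps = rng.uniform(0.01, 0.1, size=k)
    theta = rng.normal(0, 0.5, size=k)
    return theta, mu, Phi, log_q, eps


class TestRewardAndEpsilon:
    def test_reward_is_dot_product(self, rng):
        theta, phi = rng.normal(size=14), rng.uniform(size=14)
        oracle = sum(t * p for t, p in zip(theta, phi))
        assert trajectory_reward(theta, phi) == pytest.approx(oracle)
        assert trajectory_reward(np.zeros(14), phi) == 0.0

    def test_hoeffding_closed_form(self):
        eps = hoeffding_epsilon(100, k=14, delta=0.05, feature_ranges=1.0)
        assert np.allclose(eps, math.sqrt(math.log(560) / 200))

    def test_hoeffding_shrinks_with_samples_and_scales_with_range(self):
        e1 = hoeffding_epsilon(50)
        e2 = hoeffding_epsilon(200)
        assert np.all(e2 < e1)
        assert np.allclose(hoeffding_epsilon(50, feature_ranges=2.0), 2 * e1)

    def test_bernstein_uses_observed_spread(self, rng):
        Phi = rng.uniform(0, 1, size=(60, 14))
        Phi[:, 3] *= 0.01  # nearly constant feature -> much smaller slack
        eps = bernstein_epsilon(Phi)
        assert eps[3] < 0.05 * eps.mean()


class TestTrajectoryProb:
    def test_zero_theta_uniform_baseline_gives_uniform(self):
        Phi = np.ones((5, 14))
        p = trajectory_prob(np.zeros(14), Phi, np.full(5, math.log(0.2)))
        assert np.allclose(p, 0.2)

    def test_normalizes_to_one(self, rng):
        for _ in range(20):
            theta, mu, Phi, log_q, eps = _random_instance(rng)
            p = trajectory_prob(theta, Phi, log_q)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)

    def test_matches_naive_evaluation(self, rng):
        theta, _mu, Phi, log_q, _eps = _random_instance(rng, n=8)
        naive = np.exp(log_q) * np.exp(Phi @ theta)
        naive /= naive.sum()
        assert np.allclose(trajectory_prob(theta, Phi, log_q), naive, atol=1e-12)

    def test_feature_shift_cancels_in_normalization(self, rng):
        theta, _mu, Phi, log_q, _eps = _random_instance(rng)
        p1 = trajectory_prob(theta, Phi, log_q)
        p2 = trajectory_prob(theta, Phi + 0.7, log_q)
        assert np.allclose(p1, p2, atol=1e-12)


class TestDual:
    def test_value_at_zero_theta_is_minus_log_total_baseline_mass(self, rng):
        _t, mu, Phi, log_q, eps = _random_instance(rng)
        v = dual_value(np.zeros(14), mu, Phi, log_q, eps)
        assert v == pytest.approx(-math.log(np.exp(log_q).sum()))

    def test_concavity_probe(self, rng):
        for _ in range(20):
            t1, mu, Phi, log_q, eps = _random_instance(rng)
            t2 = rng.normal(0, 0.5, size=14)
            mid = dual_value((t1 + t2) / 2, mu, Phi, log_q, eps)
            ends = 0.5 * (
                dual_value(t1, mu, Phi, log_q, eps)
                + dual_value(t2, mu, Phi, log_q, eps)
            )
            assert mid >= ends - 1e-9

    def test_gradient_matches_central_finite_differences(self, rng):
        h = 1e-6
        for _ in range(20):
            theta, mu, Phi, log_q, eps = _random_instance(rng)
            theta[np.abs(theta) < 0.05] = 0.1  # stay away from the |θ| kink
            grad = dual_gradient(theta, mu, Phi, log_q, eps)
            fd = np.empty(14)
            for i in range(14):
                up, dn = theta.copy(), theta.copy()
                up[i] += h
                dn[i] -= h
                fd[i] = (
                    dual_value(up, mu, Phi, log_q, eps)
                    - dual_value(dn, mu, Phi, log_q, eps)
                ) / (2 * h)
            denom = np.maximum(np.abs(fd), 1e-8)
            assert np.max(np.abs(grad - fd) / denom) < 1e-5

    def test_sign_term_flips_with_theta(self, rng):
        _t, mu, Phi, log_q, eps = _random_instance(rng)
        theta = np.full(14, 0.3)
        g_pos = dual_gradient(theta, mu, Phi, log_q, eps)
        g_neg = dual_gradient(-theta, mu, Phi, log_q, eps)
        # the ε term subtracts for positive θ and adds for negative θ
        smooth_pos = g_pos + eps
        smooth_neg = g_neg - eps
        assert np.all(np.abs((smooth_pos - smooth_neg)) < 1.0)  # same smooth scale
        assert np.all(g_neg - g_pos > 0)  # 2ε gap in each coordinate
        assert np.allclose(g_neg - g_pos - 2 * eps, smooth_neg - smooth_pos)


class TestBaselinePolicy:
    def test_uniform_policy_interior_cells_give_log_one_ninth(self, open_plan):
        policy = BaselinePolicy(open_plan)
        assert policy.log_action_prob((3, 4), Action.NE) == pytest.approx(
            math.log(1 / 9)
        )
        # L interior steps contribute L·log(1/9)
        total = sum(policy.log_action_prob((3, 4), a) for a in [Action.N] * 5)
        assert total == pytest.approx(5 * math.log(1 / 9))

    def test_corner_cells_restrict_support(self, open_plan):
        policy = BaselinePolicy(open_plan)
        assert policy.log_action_prob((1, 1), Action.SE) == pytest.approx(
            math.log(1 / 4)
        )
        assert policy.log_action_prob((1, 1), Action.NW) == -math.inf

    def test_logprob_of_three_step_fixture(self, open_plan):
        mdp = build_mdp(open_plan)
        steps = [
            (State((3, 3), 0), Action.E),
            (State((3, 4), 0), Action.SE),
            (State((4, 5), 0), Action.STAY),
        ]
        tau = Trajectory(dt.date(2024, 1, 1), steps)
        lp = baseline_logprob(tau, mdp)
        # uniform start + deterministic nominal T + three interior action choices
        expected = math.log(1 / mdp.n_states) + 3 * math.log(1 / 9)
        assert lp == pytest.approx(expected)

    def test_zero_probability_step_flagged_as_minus_inf(self, open_plan):
        mdp = build_mdp(open_plan)
        # action E from (3,3) cannot land on (5,5) under nominal dynamics
        steps = [(State((3, 3), 0), Action.E), (State((5, 5), 0), Action.STAY)]
        assert baseline_logprob(Trajectory(dt.date(2024, 1, 1), steps), mdp) == -math.inf


class TestRoutineBaseline:
    def test_expected_features_is_gradient_of_log_z(self, prepared_home, rng):
        bl = RoutineBaseline.from_days(
            prepared_home.days, floorplan=prepared_home.floorplan
        )
        h = 1e-6
        for _ in range(5):
            theta = rng.normal(0, 5, size=14)
            expected = bl.expected_features(theta) - bl.offset
            fd = np.empty(14)
            for i in range(14):
                up, dn = theta.copy(), theta.copy()
                up[i] += h
                dn[i] -= h
                fd[i] = (bl.log_z(up) - bl.log_z(dn)) / (2 * h)
            assert np.allclose(expected, fd, rtol=1e-4, atol=1e-9)

    def test_visit_distribution_normalizes_and_tilts(self, prepared_home):
        bl = RoutineBaseline.from_days(
            prepared_home.days, floorplan=prepared_home.floorplan
        )
        p0 = bl.visit_distribution(np.zeros(14))
        assert p0.sum() == pytest.approx(1.0)
        assert np.allclose(p0, 0.1)
        theta = np.zeros(14)
        theta[4] = 50.0  # d_bedroom
        p = bl.visit_distribution(theta)
        assert p[4] > p0[4]


class TestFit:
    def test_zero_learning_rate_leaves_theta_at_init(self, prepared_home):
        cfg = IrlConfig(learn_rate=0.0, max_iter=5, seed=11)
        res = ri.fit_preferences(prepared_home, cfg)
        init = np.random.default_rng(11).normal(0.0, 0.01, size=14)
        assert np.allclose(res.theta, init)
        assert not res.converged and res.iterations == 5

    def test_same_seed_reproduces_theta(self, prepared_home):
        r1 = ri.fit_preferences(prepared_home, IrlConfig(max_iter=50))
        r2 = ri.fit_preferences(prepared_home, IrlConfig(max_iter=50))
        assert np.array_equal(r1.theta, r2.theta)

    def test_dual_trace_is_monotone_under_fixed_baseline(self, prepared_home):
        res = ri.fit_preferences(prepared_home, IrlConfig(max_iter=200))
        trace = np.array(res.dual_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_larger_mu_feature_earns_larger_weight(self, prepared_home):
        """Sanity oracle: whichever of two room features dominates behavior
        must dominate the fitted preference."""
        res = ri.fit_preferences(prepared_home, IrlConfig(max_iter=500))
        mu = np.vstack([d.phi for d in prepared_home.days]).mean(axis=0)
        i_bed, i_stove = 4, 8
        assert mu[i_bed] > mu[i_stove]
        assert res.theta[i_bed] > res.theta[i_stove]

    def test_empty_day_list_rejected(self, prepared_home):
        with pytest.raises(ValueError):
            fit([], prepared_home.mdp, IrlConfig())

    def test_sampled_rollout_mode_runs_and_traces(self, prepared_home):
        cfg = IrlConfig(sample_mode="rollout", n_samples=20, max_iter=50)
        res = fit(prepared_home.days, prepared_home.mdp, cfg)
        assert res.iterations == 50 or res.converged
        assert np.all(np.isfinite(res.theta))

    def test_observed_subset_mode_runs(self, prepared_home):
        cfg = IrlConfig(sample_mode="observed", n_samples=8, max_iter=30)
        res = fit(prepared_home.days, prepared_home.mdp, cfg)
        assert np.all(np.isfinite(res.theta))


def test_rollout_matches_day_length_and_baseline_support(prepared_home, rng):
    mdp = prepared_home.mdp
    traj, path = rollout_baseline(mdp, 50, rng)
    assert traj.n_steps == 50 and path.n_points == 50
    cells = [s.cell for s, _a in traj.steps]
    for u, v in zip(cells, cells[1:]):
        assert max(abs(u[0] - v[0]), abs(u[1] - v[1])) <= 1
    lp = baseline_logprob(traj, mdp)
    assert math.isfinite(lp) and lp < 0
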