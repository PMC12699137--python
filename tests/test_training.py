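"""Tests for return computation, normalization and the REINFORCE loop."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

import fluxrl as fx
from fluxrl.episodes import EpisodeBatch
from fluxrl.training import GradientAscent, make_optimizer, policy_gradient_step


class TestComputeReturn:
    def test_terminal_titer_of_static_fatty_acid(self, fa_model, fa_grid, titer_objective):
        sc = fx.static_policy(40.0, fa_model)
        traj = fx.rollout(sc, fa_model, fa_grid, fx.RandomizationSpec(0.0),
                          titer_objective, np.random.default_rng(0))
        J = fx.compute_return(traj, titer_objective)
        assert J == pytest.approx(1.61, abs=0.01)
        assert J == pytest.approx(traj.total_return)

    def test_tracking_constant_offset(self, lac_model, lac_grid):
        # reference shifted by delta at every step: J = -N * delta^2
        sc = fx.static_policy(873.0, lac_model)
        probe = fx.rollout(sc, lac_model, lac_grid, fx.RandomizationSpec(0.0),
                           fx.ObjectiveSpec("terminal_titer"), np.random.default_rng(0))
        E = probe.states[1:, lac_model.state_index("E")]
        delta = 0.37
        obj = fx.ObjectiveSpec("reference_tracking", reference=E + delta)
        J = fx.compute_return(probe, obj)
        assert J == pytest.approx(-lac_grid.n_intervals * delta**2, rel=1e-9)

    def test_perfect_tracking_attains_the_maximum(self, lac_model, lac_grid):
        sc = fx.static_policy(873.0, lac_model)
        probe = fx.rollout(sc, lac_model, lac_grid, fx.RandomizationSpec(0.0),
                           fx.ObjectiveSpec("terminal_titer"), np.random.default_rng(0))
        E = probe.states[1:, lac_model.state_index("E")]
        obj = fx.ObjectiveSpec("reference_tracking", reference=E)
        assert fx.compute_return(probe, obj) == pytest.approx(0.0, abs=1e-12)


class TestNormalizeReturns:
    def test_equal_returns_yield_zero_advantages(self):
        adv = fx.normalize_returns(np.array([1.0, 1.0, 1.0, 1.0]))
        assert np.all(adv == 0.0)

    def test_two_point_population_convention(self):
        adv = fx.normalize_returns(np.array([0.0, 2.0]))
        np.testing.assert_allclose(adv, [-1.0, 1.0], atol=1e-7)

    def test_advantages_are_centered(self):
        rng = np.random.default_rng(0)
        adv = fx.normalize_returns(rng.normal(5.0, 2.0, size=333))
        assert abs(adv.mean()) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fx.normalize_returns(np.array([]))


class _ToyGaussianPolicy:
    """Mean = theta, fixed sigma: score d log pi / d theta = (u - theta)/sigma^2."""

    def __init__(self, theta: float, sigma: float):
        self.mlp = SimpleNamespace(params=[np.array([theta])])
        self.sigma = sigma

    @property
    def theta(self) -> float:
        return float(self.mlp.params[0][0])

    def grad_log_policy(self, feats, u_raw, weights):
        score = (np.asarray(u_raw) - self.theta) / self.sigma**2
        return [np.array([float(np.sum(weights * score))])]


def _toy_batch(model, u_raw, returns):
    k = len(u_raw)
    rewards = np.zeros((k, 1))
    rewards[:, 0] = returns
    return EpisodeBatch(
        model=model,
        times=np.array([0.0, 1.0]),
        states=np.zeros((k, 2, model.n_states)),
        inputs=np.asarray(u_raw)[:, None],
        rewards=rewards,
        x0=np.zeros((k, model.n_states)),
        params=model.params,
        features=np.zeros((k, 1, 1)),
        raw_inputs=np.asarray(u_raw, dtype=float)[:, None],
    )


class TestPolicyGradientStep:
    def test_zero_advantages_leave_parameters_unchanged(self, fa_model):
        pol = _ToyGaussianPolicy(theta=3.0, sigma=1.0)
        batch = _toy_batch(fa_model, [2.0, 4.0, 1.0], [5.0, 5.0, 5.0])
        policy_gradient_step(batch, pol, GradientAscent(0.1))
        assert pol.theta == 3.0

    def test_update_matches_closed_form_estimator(self, fa_model):
        # two episodes, one step each: update = alpha * mean(adv_k * score_k)
        theta0, sigma, alpha = 3.0, 2.0, 0.05
        u = np.array([1.0, 6.0])
        J = np.array([0.0, 2.0])
        pol = _ToyGaussianPolicy(theta0, sigma)
        batch = _toy_batch(fa_model, u, J)
        policy_gradient_step(batch, pol, GradientAscent(alpha), eps_mach=0.0)
        adv = (J - J.mean()) / J.std()
        expected = theta0 + alpha * np.mean(adv * (u - theta0) / sigma**2)
        assert pol.theta == pytest.approx(expected, rel=1e-12)

    def test_full_estimator_matches_finite_differences(self, fa_model):
        # tiny network, N_MC=4 episodes x 3 steps, plain ascent
        grid = fx.ControlGrid(t_end=3.0, n_intervals=3)
        pol = fx.GaussianMLPPolicy(fa_model, grid, hidden=(4,), rng=3)
        rng = np.random.default_rng(8)
        k, n_int = 4, 3
        feats = rng.uniform(-1, 1, (k, n_int, pol.n_features))
        u_raw = rng.uniform(0, 1000, (k, n_int))
        returns = rng.normal(size=k)
        adv = fx.normalize_returns(returns)
        weights = np.repeat(adv / k, n_int)

        grads = pol.grad_log_policy(feats.reshape(-1, pol.n_features),
                                    u_raw.ravel(), weights)
        flat = np.concatenate([g.ravel() for g in grads])

        from fluxrl.policy import gaussian_log_pdf

        def estimator_objective(theta):
            pol.mlp.set_flat(theta)
            m, s = pol.action_distribution(feats.reshape(-1, pol.n_features))
            lp = gaussian_log_pdf(u_raw.ravel(), m, s).reshape(k, n_int)
            return float(np.mean(adv * lp.sum(axis=1)))

        theta0 = pol.mlp.get_flat()
        h = 1e-5
        for i in np.random.default_rng(9).choice(theta0.size, 40, replace=False):
            tp, tm = theta0.copy(), theta0.copy()
            tp[i] += h
            tm[i] -= h
            fd = (estimator_objective(tp) - estimator_objective(tm)) / (2 * h)
            assert flat[i] == pytest.approx(fd, rel=1e-4, abs=1e-12)
        pol.mlp.set_flat(theta0)

    def test_missing_records_rejected(self, fa_model):
        batch = _toy_batch(fa_model, [1.0, 2.0], [0.0, 1.0])
        batch.features = None
        pol = _ToyGaussianPolicy(0.0, 1.0)
        with pytest.raises(ValueError):
            policy_gradient_step(batch, pol, GradientAscent(0.1))


class TestEstimatorUnbiasedness:
    def test_single_step_bandit_matches_analytic_gradient(self):
        # Gaussian bandit, J(u) = u: grad_theta E[J] = 1 (mean-parameter);
        # averaging many single-episode REINFORCE estimates (no baseline)
        # must recover it within Monte-Carlo error.
        theta, sigma = 0.0, 1.0
        rng = np.random.default_rng(0)
        n = 200_000
        u = rng.normal(theta, sigma, size=n)
        estimates = u * (u - theta) / sigma**2  # J(u) * score(u)
        sem = estimates.std() / np.sqrt(n)
        assert abs(estimates.mean() - 1.0) < 3 * sem


class TestTrainLoop:
    def test_constant_return_environment_early_stops(self, lac_model, lac_grid):
        # with no biomass the lactate titer is 0 whatever the policy does
        barren = dataclasses.replace(lac_model)
        barren.x0 = np.array([4.0, 0.0, 0.0, 0.0])
        cfg = fx.TrainingConfig(learning_rate=0.01, epochs=50, episodes_per_epoch=4,
                                patience=3, seed=0)
        res = fx.train(barren, lac_grid, fx.RandomizationSpec(0.0),
                       fx.ObjectiveSpec("terminal_titer"), cfg)
        assert res.termination == "early_stop"
        # first epoch improves on -inf; then `patience` stalled epochs
        assert len(res.epoch_log) == 1 + cfg.patience
        assert res.best_epoch == 0

    def test_same_seed_reproduces_epoch_log(self, fa_model):
        grid = fx.ControlGrid(t_end=5.0, n_intervals=5)
        cfg = fx.TrainingConfig(learning_rate=0.0075, epochs=4, episodes_per_epoch=8,
                                seed=123)
        obj = fx.ObjectiveSpec("terminal_titer")
        r1 = fx.train(fa_model, grid, fx.RandomizationSpec(0.1), obj, cfg)
        r2 = fx.train(fa_model, grid, fx.RandomizationSpec(0.1), obj, cfg)
        assert r1.log_frame().equals(r2.log_frame())
        assert np.array_equal(r1.policy.mlp.get_flat(), r2.policy.mlp.get_flat())

    def test_selected_epoch_has_maximal_mean_return(self, fa_training_det):
        means = [e.mean_return for e in fa_training_det.epoch_log]
        assert fa_training_det.best_mean_return == max(means)
        assert fa_training_det.epoch_log[fa_training_det.best_epoch].best_so_far

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            fx.TrainingConfig(learning_rate=0.0, epochs=10, episodes_per_epoch=10)
        with pytest.raises(ValueError):
            fx.TrainingConfig(learning_rate=0.1, epochs=10, episodes_per_epoch=1)
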