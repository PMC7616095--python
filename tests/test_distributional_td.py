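"""Distributional TD model: update rules, expectile stationarity, grid
fitting, and agent evaluation."""
import numpy as np
import pytest

from dopadist.distributional_td import (
    TDConfig,
    apply_update,
    build_projection_agents,
    estimate_activity_distribution,
    evaluate_agent,
    expectile_oracle,
    fit_learning_rates,
    make_agent,
    stationary_td_error,
    td_error,
    train_agent,
)


class TestUpdateRules:
    @pytest.mark.parametrize("v_t,r,gamma,v_next,expected", [
        (2.0, 0.0, 1.0, 5.0, 3.0),
        (4.0, 5.0, 0.9, 0.0, 1.0),
        (3.7, 1.0, 0.5, 5.4, 0.0),          # v_t = r + gamma v_next
    ])
    def test_td_error_arithmetic(self, v_t, r, gamma, v_next, expected):
        assert td_error(v_t, r, gamma, v_next) == pytest.approx(expected)

    @pytest.mark.parametrize("v,delta,ap,am,expected", [
        (2.0, 3.0, 0.5, 0.1, 3.5),
        (2.0, -2.0, 0.5, 0.25, 1.5),
        (2.0, 0.0, 0.5, 0.25, 2.0),          # zero error: no update
    ])
    def test_asymmetric_update(self, v, delta, ap, am, expected):
        assert apply_update(v, delta, ap, am) == pytest.approx(expected)


class TestExpectileOracle:
    def test_tau_half_is_mean(self):
        assert expectile_oracle(0.5, 5.0, 5.0) == pytest.approx(5.0, abs=1e-8)

    @pytest.mark.parametrize("tau", [0.1, 0.25, 0.4])
    def test_antisymmetry_around_zero_mean(self, tau):
        e1 = expectile_oracle(tau, 0.0, 2.0)
        e2 = expectile_oracle(1.0 - tau, 0.0, 2.0)
        assert e1 == pytest.approx(-e2, abs=1e-8)

    def test_matches_stochastic_approximation(self):
        """Brute-force oracle: the asymmetric update iterated with decaying
        rates converges to the closed-form expectile."""
        rng = np.random.default_rng(0)
        tau, mu, sigma = 0.7, 5.0, 5.0
        v = 0.0
        n = 200_000
        xs = rng.normal(mu, sigma, n)
        for i, x in enumerate(xs):
            delta = x - v
            rate = 5.0 / (100.0 + i)
            v += rate * (tau * delta if delta > 0 else (1 - tau) * delta)
        assert v == pytest.approx(expectile_oracle(tau, mu, sigma), abs=0.15)

    def test_monotone_in_tau(self):
        es = [expectile_oracle(t, 5.0, 5.0) for t in np.linspace(0.05, 0.95, 10)]
        assert np.all(np.diff(es) > 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            expectile_oracle(0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            expectile_oracle(0.5, 0.0, -1.0)


class TestTraining:
    def test_balanced_rates_converge_to_training_mean(self):
        cfg = TDConfig()
        rng = np.random.default_rng(1)
        a = rng.uniform(0.0, 1.0, cfg.n_neurons)
        agent = make_agent(cfg, rng, a, a)
        train_agent(agent, cfg, rng)
        mean_v = agent.converged_V[:, cfg.reward_state].mean()
        assert mean_v == pytest.approx(5.0, abs=0.15)

    @pytest.mark.parametrize("tau", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_converged_value_equals_expectile(self, tau):
        """Stationarity: reward-state value matches the tau-expectile of the
        training distribution for tau = a+/(a+ + a-)."""
        cfg = TDConfig(n_neurons=30, n_training_trials=20_000)
        rng = np.random.default_rng(int(tau * 100))
        # small total rate: the stationary point approaches the expectile
        # as the learning rates shrink
        s = 0.1
        agent = make_agent(cfg, rng, np.full(cfg.n_neurons, s * tau),
                           np.full(cfg.n_neurons, s * (1 - tau)))
        train_agent(agent, cfg, rng)
        oracle = expectile_oracle(tau, 5.0, 5.0)
        assert agent.converged_V[:, cfg.reward_state].mean() == \
            pytest.approx(oracle, abs=0.35)

    def test_value_monotone_in_asymmetry(self):
        cfg = TDConfig(n_neurons=9)
        rng = np.random.default_rng(3)
        taus = np.linspace(0.1, 0.9, 9)
        agent = make_agent(cfg, rng, 0.2 * taus / 0.5, 0.2 * (1 - taus) / 0.5)
        train_agent(agent, cfg, rng)
        v = agent.converged_V[:, cfg.reward_state]
        assert np.all(np.diff(v) > 0)

    def test_gamma_k_value_propagation(self):
        """With a deterministic chain, the value k steps before reward is
        gamma^k times the reward-state value."""
        cfg = TDConfig(gamma=0.8)
        rng = np.random.default_rng(4)
        a = np.full(cfg.n_neurons, 0.2)
        agent = make_agent(cfg, rng, a, a)
        train_agent(agent, cfg, rng)
        v = agent.converged_V.mean(axis=0)
        for k in range(1, cfg.n_states):
            assert v[cfg.reward_state - k] == \
                pytest.approx(0.8**k * v[cfg.reward_state], rel=0.05)

    def test_degenerate_reward_converges_exactly(self):
        cfg = TDConfig(reward_sd=1e-12, n_neurons=10, n_training_trials=2000,
                       test_range=(5.0, 5.0), n_test_rewards=10)
        rng = np.random.default_rng(5)
        agent = make_agent(cfg, rng)
        train_agent(agent, cfg, rng)
        np.testing.assert_allclose(agent.converged_V[:, cfg.reward_state], 5.0,
                                   atol=1e-6)
        ev = evaluate_agent(agent, cfg, rng)
        assert ev.mean_mse == pytest.approx(0.0, abs=1e-10)

    def test_divergence_guard(self):
        cfg = TDConfig(n_training_trials=100)
        rng = np.random.default_rng(6)
        agent = make_agent(cfg, rng)
        agent.V += np.inf
        with pytest.raises(FloatingPointError):
            train_agent(agent, cfg, rng)


class TestActivityDistribution:
    def test_density_integrates_to_one(self):
        x = np.random.default_rng(0).normal(0, 1, 200)
        act = estimate_activity_distribution(x)
        area = np.trapezoid(act.density, act.grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_draw_mean_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 1.0, 500)
        act = estimate_activity_distribution(x)
        draws = act.draw(100_000, np.random.default_rng(2))
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - x.mean()) < 3 * se + 1e-3

    def test_degenerate_sample_flagged(self):
        act = estimate_activity_distribution(np.full(10, 3.0))
        assert act.degenerate
        draws = act.draw(1000, np.random.default_rng(3))
        assert draws.std() < 5 * act.bandwidth
        assert draws.mean() == pytest.approx(3.0, abs=1e-3)

    def test_too_few_responses_rejected(self):
        with pytest.raises(ValueError):
            estimate_activity_distribution(np.array([1.0, 2.0]))


class TestGridFit:
    def test_symmetric_targets_give_balanced_asymmetry(self):
        cfg = TDConfig()
        act = estimate_activity_distribution(
            np.random.default_rng(0).normal(0, 1, 400), "sym")
        fit = fit_learning_rates(act, cfg, np.random.default_rng(1))
        assert fit.asymmetry.mean() == pytest.approx(0.5, abs=0.05)

    def test_positive_targets_give_pessimistic_fits(self):
        """A persistently positive reward-state TD error implies a value
        below the mean, i.e. asymmetry < 0.5."""
        cfg = TDConfig()
        act = estimate_activity_distribution(
            np.abs(np.random.default_rng(2).normal(0, 1, 400)) + 0.5, "pos")
        fit = fit_learning_rates(act, cfg, np.random.default_rng(3))
        positive = fit.targets > 0.1
        assert positive.sum() >= 40
        assert np.all(fit.asymmetry[positive] < 0.5)

    def test_zero_target_fits_balanced_to_grid_resolution(self):
        cfg = TDConfig()
        act = estimate_activity_distribution(np.zeros(10), "deg")
        fit = fit_learning_rates(act, cfg, np.random.default_rng(4))
        np.testing.assert_allclose(fit.asymmetry, 0.5, atol=0.02)

    def test_stationary_error_sign_convention(self):
        # optimistic tau -> value above mean -> negative stationary error
        assert stationary_td_error(0.9, 5.0, 5.0) < 0
        assert stationary_td_error(0.1, 5.0, 5.0) > 0
        assert stationary_td_error(0.5, 5.0, 5.0) == pytest.approx(0.0, abs=1e-6)


class TestEvaluation:
    def test_mse_identity_and_nonnegativity(self):
        cfg = TDConfig(n_neurons=5, n_test_rewards=50)
        rng = np.random.default_rng(7)
        agent = make_agent(cfg, rng)
        agent.converged_V = np.tile(np.linspace(2, 8, 5)[:, None], (1, cfg.n_states))
        ev = evaluate_agent(agent, cfg, rng)
        manual = np.mean((ev.test_rewards[None, :] - ev.predictions[:, None]) ** 2,
                         axis=1)
        np.testing.assert_allclose(ev.mse_per_cell, manual)
        assert np.all(ev.mse_per_cell >= 0)

    def test_underestimation_for_positive_target_fits(self):
        """Agents fit to strictly positive activity targets predict below
        the training mean (systematic underestimation)."""
        cfg = TDConfig()
        act = estimate_activity_distribution(
            np.abs(np.random.default_rng(8).normal(0, 1, 300)) + 0.5, "pos")
        rng = np.random.default_rng(9)
        fit = fit_learning_rates(act, cfg, rng)
        agent = make_agent(cfg, rng, fit.alpha_plus, fit.alpha_minus)
        train_agent(agent, cfg, rng)
        assert agent.converged_V[:, cfg.reward_state].mean() < 5.0

    def test_untrained_agent_rejected(self):
        cfg = TDConfig()
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            evaluate_agent(make_agent(cfg, rng), cfg, rng)


class TestProjectionAgents:
    def test_five_agents_of_fifty_neurons(self):
        cfg = TDConfig(n_training_trials=2000)
        rng = np.random.default_rng(11)
        samples = {p: rng.normal(0, 1, 30) for p in ("DMS", "DLS", "VLS", "NAcCore")}
        agents = build_projection_agents(samples, cfg, rng)
        assert set(agents) == {"DMS", "DLS", "VLS", "NAcCore", "unified"}
        assert all(a.n_neurons == 50 for a, _ in agents.values())

    def test_unified_sample_is_concatenation(self):
        cfg = TDConfig(n_training_trials=500, n_neurons=10)
        rng = np.random.default_rng(12)
        samples = {"A": np.arange(10.0), "B": np.arange(10.0, 18.0)}
        agents = build_projection_agents(samples, cfg, rng, train=False)
        # activity sample used for the unified agent pools both populations
        assert agents["unified"][1].targets.size == cfg.n_neurons
        pooled = np.concatenate([samples["A"], samples["B"]])
        assert agents["unified"][1].targets.min() >= pooled.min() - 5
        assert agents["unified"][1].targets.max() <= pooled.max() + 5

    def test_identical_populations_indistinguishable(self):
        from scipy import stats
        cfg = TDConfig(n_training_trials=500)
        rng = np.random.default_rng(13)
        base = np.random.default_rng(14).normal(0, 1, 60)
        agents = build_projection_agents({"A": base, "B": base.copy()}, cfg, rng,
                                         train=False)
        p = stats.ks_2samp(agents["A"][1].asymmetry, agents["B"][1].asymmetry).pvalue
        assert p > 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_projection_agents({}, TDConfig(), np.random.default_rng(0))
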