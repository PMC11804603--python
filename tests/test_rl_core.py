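"""Behavioral layer: delta-rule arithmetic, simulation contracts, and the
prediction-error-variance phenomenology that drives the scenario suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from latentsim import (
    RLParams,
    TaskConfig,
    compute_pe,
    effective_alpha,
    pe_variance,
    simulate_agent,
    softmax_prob,
    update_value,
)


class TestDeltaRuleArithmetic:
    @pytest.mark.parametrize(
        "outcome, value, gamma, expected",
        [
            (1.0, 0.5, 1.0, 0.5),
            (1.0, 0.525, 1.0, 0.475),
            (1.0, 0.75, 1.0, 0.25),
            (1.0, 0.5, 2.0, 1.5),
        ],
    )
    def test_prediction_error(self, outcome, value, gamma, expected):
        assert compute_pe(outcome, value, gamma) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10, allow_nan=False))
    def test_perfectly_predicted_outcome_gives_zero_pe(self, o):
        assert compute_pe(o, o, 1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "value, alpha, pe, expected",
        [(0.5, 0.05, 0.5, 0.525), (0.5, 0.5, 0.5, 0.75), (0.37, 0.9, 0.0, 0.37)],
    )
    def test_value_update(self, value, alpha, pe, expected):
        assert update_value(value, alpha, pe) == pytest.approx(expected, abs=1e-12)

    def test_update_rejects_alpha_outside_unit_interval(self):
        with pytest.raises(ValueError):
            update_value(0.5, 1.2, 0.1)
        with pytest.raises(ValueError):
            update_value(0.5, -0.1, 0.1)

    def test_pe_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            compute_pe(1.0, 0.5, 0.0)


class TestSoftmax:
    @given(st.floats(-5, 5), st.floats(0, 20))
    def test_equal_values_give_indifference(self, v, beta):
        assert softmax_prob(v, v, beta) == pytest.approx(0.5)

    def test_zero_beta_is_indifference(self):
        assert softmax_prob(1.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_deterministic_limit(self):
        assert softmax_prob(1.0, 0.0, 100.0) == pytest.approx(1.0, abs=1e-10)

    def test_overflow_safe(self):
        # saturates instead of overflowing for extreme value differences
        assert softmax_prob(1e6, -1e6, 50.0) == 1.0
        assert softmax_prob(-1e6, 1e6, 50.0) == 0.0

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            softmax_prob(1.0, 0.0, -1.0)


class TestEffectiveAlpha:
    def test_zero_decay_is_static(self):
        assert effective_alpha(0.5, 0.0, 57) == 0.5

    def test_first_trial_unchanged(self):
        assert effective_alpha(0.5, 0.3, 1) == 0.5

    def test_closed_form(self):
        assert effective_alpha(0.4, 0.01, 101) == pytest.approx(0.4 * np.exp(-1.0))

    def test_non_increasing(self):
        t = np.arange(1, 200)
        a = effective_alpha(0.3, 0.02, t)
        assert np.all(np.diff(a) <= 0)


class TestSimulateAgent:
    def test_worked_example_chain(self):
        # two consecutive rewards of 1 starting from value 0.5, alpha=0.5
        task = TaskConfig(n_trials=2, mode="pavlovian")
        data = simulate_agent(
            task, RLParams(alpha=0.5, beta=0.0), seed=0, outcome_schedule=[1.0, 1.0]
        )
        assert data.pe == pytest.approx([0.5, 0.25])
        final = update_value(data.values[-1, 0], 0.5, data.pe[-1])
        assert final == pytest.approx(0.875)

    def test_no_learning_at_alpha_zero(self):
        task = TaskConfig(n_trials=50)
        params = RLParams(alpha=0.0, beta=1.0, v0=0.5)
        data = simulate_agent(task, params, seed=3)
        assert np.all(data.values == 0.5)
        assert data.pe == pytest.approx(data.outcomes - 0.5)

    def test_determinism(self):
        task = TaskConfig(n_trials=200)
        params = RLParams(alpha=0.3, beta=2.0)
        a = simulate_agent(task, params, seed=11)
        b = simulate_agent(task, params, seed=11)
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.outcomes, b.outcomes)
        assert np.array_equal(a.pe, b.pe)

    def test_pavlovian_outcomes_shared_across_learning_rates(self):
        task = TaskConfig(n_trials=300, mode="pavlovian")
        low = simulate_agent(task, RLParams(alpha=0.05, beta=0.0), seed=5)
        high = simulate_agent(task, RLParams(alpha=0.5, beta=0.0), seed=5)
        assert np.array_equal(low.outcomes, high.outcomes)
        assert not np.allclose(low.pe, high.pe)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(n_trials=10, mode="operant")

    def test_pe_matches_gamma_identity(self):
        task = TaskConfig(n_trials=100)
        params = RLParams(alpha=0.2, beta=1.0, gamma=2.0)
        data = simulate_agent(task, params, seed=9)
        expected = params.gamma * data.outcomes - data.value_chosen
        assert data.pe == pytest.approx(expected, abs=1e-12)


class TestOutcomeSensitivityEquivalence:
    @pytest.mark.parametrize("beta, gamma", [(2.0, 3.0), (0.7, 0.5), (1.0, 4.0)])
    def test_choice_probabilities_identical_under_product(self, beta, gamma):
        """(beta, gamma) and (beta*gamma, 1) generate identical choice
        probability sequences when values carry the gamma scaling."""
        task = TaskConfig(n_trials=400)
        a = simulate_agent(task, RLParams(alpha=0.15, beta=beta, gamma=gamma), seed=21)
        b = simulate_agent(task, RLParams(alpha=0.15, beta=beta * gamma, gamma=1.0), seed=21)
        assert np.array_equal(a.choices, b.choices)
        np.testing.assert_allclose(a.choice_probs, b.choice_probs, atol=1e-12)


class TestPEVariance:
    def test_hand_computed_sample_variance(self):
        task = TaskConfig(n_trials=2, mode="pavlovian")
        data = simulate_agent(
            task, RLParams(alpha=0.5, beta=0.0), seed=0, outcome_schedule=[1.0, 1.0]
        )
        # pe = [0.5, 0.25]; sample (n-1) variance = 0.03125
        assert pe_variance(data) == pytest.approx(0.03125)

    def test_constant_series_has_zero_variance(self):
        task = TaskConfig(n_trials=10)
        data = simulate_agent(task, RLParams(alpha=0.0, beta=0.0, v0=0.0), seed=1,
                              outcome_schedule=np.ones(10))
        assert pe_variance(data) == 0.0

    def test_requires_two_trials(self):
        task = TaskConfig(n_trials=1, mode="pavlovian")
        data = simulate_agent(task, RLParams(alpha=0.1, beta=0.0), seed=0)
        with pytest.raises(ValueError):
            pe_variance(data)

    def test_higher_learning_rate_gives_more_variable_pe(self):
        """Mean PE variance over 50 yoked replicates is larger at
        alpha=0.5 than at alpha=0.05."""
        task = TaskConfig(n_trials=100, mode="pavlovian")
        lows, highs = [], []
        for seed in range(50):
            lows.append(pe_variance(simulate_agent(task, RLParams(alpha=0.05, beta=0.0), seed)))
            highs.append(pe_variance(simulate_agent(task, RLParams(alpha=0.5, beta=0.0), seed)))
        assert np.mean(highs) > np.mean(lows)

    def test_no_systematic_beta_dependence(self):
        """PE variance carries no systematic inverse-temperature signal:
        |Spearman rho| < 0.15 across 120 datasets of 1000 trials."""
        task = TaskConfig(n_trials=1000)
        betas = np.tile(np.linspace(0.5, 8.0, 12), 10)
        ss = np.random.SeedSequence(2024)
        variances = [
            pe_variance(simulate_agent(task, RLParams(alpha=0.1, beta=float(b)),
                                       np.random.default_rng(child)))
            for b, child in zip(betas, ss.spawn(betas.size))
        ]
        rho = spearmanr(betas, variances).statistic
        assert abs(rho) < 0.15
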