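"""Likelihoods, MLE fitting, shared-parameter fits and the
beta/gamma identifiability ridge."""

import numpy as np
import pytest

from latentsim import (
    ModelSpec,
    RLParams,
    TaskConfig,
    fit_mle,
    fit_shared,
    neg_log_likelihood,
    predicted_pe,
    simulate_agent,
)


class TestNegLogLikelihood:
    def test_single_trial_equal_values(self):
        task = TaskConfig(n_trials=1)
        data = simulate_agent(task, RLParams(alpha=0.1, beta=1.0), seed=0)
        nll = neg_log_likelihood({"alpha": 0.1, "beta": 1.0}, data)
        assert nll == pytest.approx(np.log(2), abs=1e-12)

    def test_indifferent_chooser(self, choice_data):
        nll = neg_log_likelihood({"alpha": 0.3, "beta": 0.0}, choice_data)
        assert nll == pytest.approx(choice_data.n_trials * np.log(2), abs=1e-9)

    def test_beta_gamma_enter_only_as_product(self, choice_data):
        a = neg_log_likelihood({"alpha": 0.1, "beta": 2.0, "gamma": 3.0}, choice_data)
        b = neg_log_likelihood({"alpha": 0.1, "beta": 6.0, "gamma": 1.0}, choice_data)
        assert a == pytest.approx(b, abs=1e-10)

    def test_profile_ridge_is_constant(self, choice_data):
        """The nll is constant along {beta * gamma = c}: outcome
        sensitivity is not identifiable from choices."""
        c = 3.0
        gammas = np.linspace(0.5, 6.0, 9)
        nlls = [
            neg_log_likelihood({"alpha": 0.1, "beta": c / g, "gamma": g}, choice_data)
            for g in gammas
        ]
        assert np.ptp(nlls) < 1e-8

    def test_pavlovian_data_rejected(self):
        task = TaskConfig(n_trials=20, mode="pavlovian")
        data = simulate_agent(task, RLParams(alpha=0.1, beta=0.0), seed=0)
        with pytest.raises(ValueError):
            neg_log_likelihood({"alpha": 0.1, "beta": 1.0}, data)


class TestModelSpec:
    def test_beta_and_gamma_may_not_both_be_free(self):
        with pytest.raises(ValueError):
            ModelSpec("gamma_rw", free_params=("alpha", "beta", "gamma"))

    def test_free_and_fixed_must_cover_family(self):
        with pytest.raises(ValueError):
            ModelSpec("static_rw", free_params=("alpha",))

    def test_shared_must_be_free(self):
        with pytest.raises(ValueError):
            ModelSpec(
                "static_rw",
                free_params=("beta",),
                fixed_params={"alpha": 0.1},
                shared_across_subjects=("alpha",),
            )

    def test_gamma_fixed_at_one_is_standard_model(self, choice_data):
        spec = ModelSpec("gamma_rw", free_params=("alpha", "beta"), fixed_params={"gamma": 1.0})
        a = neg_log_likelihood({"alpha": 0.2, "beta": 1.0}, choice_data, spec)
        b = neg_log_likelihood({"alpha": 0.2, "beta": 1.0}, choice_data, ModelSpec())
        assert a == b


class TestFitMLE:
    def test_all_fixed_spec_echoes_values(self, short_choice_data):
        spec = ModelSpec(
            "static_rw", free_params=(), fixed_params={"alpha": 0.2, "beta": 1.5}
        )
        res = fit_mle(short_choice_data, spec)
        assert res.estimates["alpha"] == 0.2
        assert res.estimates["beta"] == 1.5
        assert res.neg_log_likelihood == pytest.approx(
            neg_log_likelihood(res.estimates, short_choice_data)
        )

    def test_parameter_recovery(self):
        """Median recovery error over 20 replicates of 1000 trials stays
        within +-0.05 for alpha and +-0.3 for beta."""
        task = TaskConfig(n_trials=1000)
        true = RLParams(alpha=0.1, beta=1.0)
        a_err, b_err = [], []
        for seed in range(20):
            data = simulate_agent(task, true, seed=seed)
            res = fit_mle(data, ModelSpec(), n_restarts=5, seed=seed)
            a_err.append(res.estimates["alpha"] - true.alpha)
            b_err.append(res.estimates["beta"] - true.beta)
        assert abs(np.median(a_err)) < 0.05
        assert abs(np.median(b_err)) < 0.3

    def test_unmodeled_outcome_sensitivity_inflates_beta(self):
        """Fitting gamma=1 to gamma=2 data pushes the sensitivity into
        the estimated inverse temperature."""
        task = TaskConfig(n_trials=800)
        inflated, matched = [], []
        for seed in range(5):
            d2 = simulate_agent(task, RLParams(alpha=0.1, beta=1.0, gamma=2.0), seed=seed)
            d1 = simulate_agent(task, RLParams(alpha=0.1, beta=1.0, gamma=1.0), seed=seed)
            inflated.append(fit_mle(d2, ModelSpec(), n_restarts=4, seed=seed).estimates["beta"])
            matched.append(fit_mle(d1, ModelSpec(), n_restarts=4, seed=seed).estimates["beta"])
        assert np.mean(inflated) > np.mean(matched)

    def test_degenerate_choices_flagged(self):
        task = TaskConfig(n_trials=60)
        data = simulate_agent(task, RLParams(alpha=0.1, beta=50.0, v0=0.0), seed=2)
        data.choices[:] = 0  # force all-identical choices
        res = fit_mle(data, ModelSpec(), n_restarts=3, seed=0)
        assert res.non_identified
        assert not res.converged

    def test_deterministic_given_seed(self, short_choice_data):
        a = fit_mle(short_choice_data, ModelSpec(), n_restarts=4, seed=42)
        b = fit_mle(short_choice_data, ModelSpec(), n_restarts=4, seed=42)
        assert a.estimates == b.estimates

    def test_pe_hat_consistent_with_estimates(self, short_choice_data):
        res = fit_mle(short_choice_data, ModelSpec(), n_restarts=4, seed=1)
        np.testing.assert_allclose(
            res.pe_hat, predicted_pe(res.estimates, short_choice_data)
        )


class TestFitShared:
    def _spec(self):
        return ModelSpec(
            "static_rw", free_params=("alpha", "beta"), shared_across_subjects=("alpha",)
        )

    def test_identical_datasets_match_individual_fit(self, short_choice_data):
        ind = fit_mle(short_choice_data, ModelSpec(), n_restarts=4, seed=0)
        sha = fit_shared([short_choice_data, short_choice_data], self._spec(),
                         n_restarts=4, seed=0)
        assert sha[0].estimates["alpha"] == sha[1].estimates["alpha"]
        assert sha[0].estimates["alpha"] == pytest.approx(ind.estimates["alpha"], abs=1e-3)

    def test_shared_alpha_brackets_subject_alphas(self):
        task = TaskConfig(n_trials=600)
        low = simulate_agent(task, RLParams(alpha=0.05, beta=2.0), seed=1)
        high = simulate_agent(task, RLParams(alpha=0.5, beta=2.0), seed=2)
        res = fit_shared([low, high], self._spec(), n_restarts=4, seed=0)
        a = res[0].estimates["alpha"]
        assert res[1].estimates["alpha"] == a
        assert 0.05 < a < 0.5

    def test_shared_pe_differs_from_individual_for_mismatched_subject(self):
        task = TaskConfig(n_trials=300)
        low = simulate_agent(task, RLParams(alpha=0.05, beta=2.0), seed=3)
        high = simulate_agent(task, RLParams(alpha=0.5, beta=2.0), seed=4)
        shared = fit_shared([low, high], self._spec(), n_restarts=4, seed=0)
        ind = fit_mle(low, ModelSpec(), n_restarts=4, seed=0)
        assert not np.allclose(shared[0].pe_hat, ind.pe_hat)

    def test_empty_subject_list_rejected(self):
        with pytest.raises(ValueError):
            fit_shared([], self._spec())
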