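"""Constrained maximum-likelihood estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from klchoice import (
    ModelSpec,
    Option,
    PrecisionMode,
    PrecisionPrior,
    TrialOffer,
    UtilityProfile,
    Valuation,
    choice_probabilities,
)
from klchoice.fitting import (
    FIXED_ALPHA,
    SubjectFit,
    TrialMatrix,
    fit_subject,
    negative_log_likelihood,
    rating_correlation,
)
from klchoice.synth import AgentSpec, DesignSpec, emit_ratings, generate_design, simulate_choices

from conftest import random_option, random_profile


def _dataset(profile, valuation=Valuation.KL_CONTROL, alpha=4.0, seed=0, n_trials=300):
    agent = AgentSpec(profile, PrecisionPrior(alpha), ModelSpec(valuation))
    trials = generate_design(DesignSpec(n_trials=n_trials), profile, seed=seed)
    choices = simulate_choices(trials, agent, seed=seed + 5000)
    return agent, trials, choices


class TestNegativeLogLikelihood:
    def test_matches_trialwise_choice_rule(self, profile, kl_spec, eu_spec):
        """The vectorized likelihood equals the product of per-trial softmax
        probabilities from the core choice rule."""
        rng = np.random.default_rng(1)
        trials = [
            TrialOffer(i, random_option(rng), random_option(rng)) for i in range(1, 41)
        ]
        choices = rng.choice([-1, 1], size=40)
        params = np.concatenate(([3.3], profile.vector(6)[1:]))
        for spec in (kl_spec, eu_spec):
            matrix = TrialMatrix.build(trials, choices, 6)
            fast = negative_log_likelihood(params, matrix, spec)
            slow = 0.0
            for t, c in zip(trials, choices):
                p_left, p_right = choice_probabilities(
                    t, profile, PrecisionPrior(3.3), spec
                )
                slow -= math.log(p_left if c == 1 else p_right)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_symmetric_trials_give_coin_flip_likelihood(self, kl_spec):
        trials = [TrialOffer(i, Option([2, 3]), Option([2, 3])) for i in range(1, 51)]
        choices = np.resize([1, -1], 50)
        matrix = TrialMatrix.build(trials, choices, 6)
        params = np.array([2.0, 1.0, -1.0, 2.0, 0.5, -0.5])
        assert negative_log_likelihood(params, matrix, kl_spec) == pytest.approx(
            50 * math.log(2)
        )

    def test_true_parameters_beat_perturbed_ones_on_average(self, profile, kl_spec):
        deltas = []
        for seed in range(10):
            _, trials, choices = _dataset(profile, seed=seed)
            matrix = TrialMatrix.build(trials, choices, 6)
            truth = np.concatenate(([4.0], profile.vector(6)[1:]))
            perturbed = truth + np.array([1.0, 2.0, -2.0, 1.5, -1.0, 1.0])
            perturbed = np.clip(perturbed, [2, -10, -10, -10, -10, -10], [8, 10, 10, 10, 10, 10])
            deltas.append(
                negative_log_likelihood(perturbed, matrix, kl_spec)
                - negative_log_likelihood(truth, matrix, kl_spec)
            )
        assert np.mean(deltas) > 0

    def test_out_of_box_parameters_raise(self, kl_spec):
        trials = [TrialOffer(1, Option([1]), Option([2]))]
        matrix = TrialMatrix.build(trials, np.array([1.0]), 6)
        with pytest.raises(ValueError):
            negative_log_likelihood(np.array([9.0, 0, 0, 0, 0, 0]), matrix, kl_spec)
        with pytest.raises(ValueError):
            negative_log_likelihood(np.array([4.0, 11.0, 0, 0, 0, 0]), matrix, kl_spec)

    def test_kl_and_eu_identical_on_cardinality_matched_trials(self, kl_spec, eu_spec):
        rng = np.random.default_rng(2)
        trials = []
        for i in range(1, 31):
            k = int(rng.integers(1, 5))
            trials.append(
                TrialOffer(
                    i,
                    Option(rng.choice(np.arange(1, 7), k, replace=False).tolist()),
                    Option(rng.choice(np.arange(1, 7), k, replace=False).tolist()),
                )
            )
        choices = rng.choice([-1, 1], size=30)
        matrix = TrialMatrix.build(trials, choices, 6)
        params = np.array([3.0, 1.0, 2.0, -1.0, 0.5, -2.0])
        assert negative_log_likelihood(params, matrix, kl_spec) == pytest.approx(
            negative_log_likelihood(params, matrix, eu_spec), abs=1e-10
        )


class TestFitSubject:
    def test_recovers_generating_parameters(self, profile, kl_spec):
        """Median recovery over a handful of simulated subjects."""
        corrs, alpha_errs = [], []
        for seed in range(5):
            _, trials, choices = _dataset(profile, seed=11 + seed)
            fit = fit_subject(trials, choices, kl_spec, n_restarts=8, seed=1 + seed)
            truth = profile.vector(6)
            estimate = fit.utilities_hat.vector(6)
            corrs.append(np.corrcoef(truth, estimate)[0, 1])
            alpha_errs.append(abs(fit.alpha_hat - 4.0))
        assert np.median(corrs) > 0.9
        assert np.median(alpha_errs) < 1.5

    def test_respects_boxes_and_pins_reference_outcome(self, profile, kl_spec):
        _, trials, choices = _dataset(profile, seed=12, n_trials=100)
        fit = fit_subject(trials, choices, kl_spec, n_restarts=4, seed=2)
        assert fit.utilities_hat[1] == 0.0
        assert 2.0 <= fit.alpha_hat <= 8.0
        assert all(-10.0 <= fit.utilities_hat[o] <= 10.0 for o in range(2, 7))

    def test_fixed_precision_variant_has_five_parameters(self, profile):
        spec = ModelSpec(Valuation.KL_CONTROL, PrecisionMode.FIXED)
        _, trials, choices = _dataset(profile, seed=13, n_trials=100)
        fit = fit_subject(trials, choices, spec, n_restarts=4, seed=3)
        assert fit.alpha_hat == FIXED_ALPHA
        assert fit.n_params == 5

    def test_estimated_variant_has_six_parameters_and_bic_penalty(self, profile, kl_spec):
        _, trials, choices = _dataset(profile, seed=14, n_trials=100)
        fit = fit_subject(trials, choices, kl_spec, n_restarts=4, seed=4)
        assert fit.n_params == 6
        assert fit.bic_score == pytest.approx(
            fit.log_likelihood - 3.0 * math.log(100)
        )

    def test_deterministic_under_seed(self, profile, kl_spec):
        _, trials, choices = _dataset(profile, seed=15, n_trials=100)
        a = fit_subject(trials, choices, kl_spec, n_restarts=3, seed=5)
        b = fit_subject(trials, choices, kl_spec, n_restarts=3, seed=5)
        assert a.alpha_hat == b.alpha_hat
        assert a.utilities_hat == b.utilities_hat

    def test_extreme_preferences_pin_to_box_boundary(self, kl_spec):
        # a very strong preference saturates at the +/-10 bound, as seen in
        # fitted tables where entries print exactly -10.00
        strong = UtilityProfile.from_vector([0.0, 10.0, -10.0, 0.0, 0.0, 0.0])
        agent = AgentSpec(strong, PrecisionPrior(8.0), kl_spec)
        trials = generate_design(DesignSpec(n_trials=400), strong, seed=16)
        choices = simulate_choices(trials, agent, seed=17)
        fit = fit_subject(trials, choices, kl_spec, n_restarts=6, seed=6)
        assert fit.utilities_hat[2] > 8.0
        assert fit.utilities_hat[3] < -8.0

    def test_few_trials_warn(self, profile, kl_spec):
        _, trials, choices = _dataset(profile, seed=18, n_trials=40)
        with pytest.warns(RuntimeWarning):
            fit_subject(trials[:20], choices.head(20), kl_spec, n_restarts=2, seed=7)

    def test_model_recovery_eu_data_favors_eu_fit(self, profile, eu_spec, kl_spec):
        diffs = []
        for seed in range(6):
            _, trials, choices = _dataset(
                profile, valuation=Valuation.EXPECTED_UTILITY, seed=30 + seed
            )
            eu_fit = fit_subject(trials, choices, eu_spec, n_restarts=5, seed=seed)
            kl_fit = fit_subject(trials, choices, kl_spec, n_restarts=5, seed=seed)
            diffs.append(eu_fit.bic_score - kl_fit.bic_score)
        assert np.mean(diffs) > 0


class TestIdentifiability:
    def test_likelihood_invariant_to_utility_shift_when_unpinned(self, kl_spec):
        """Shifting every utility (including the reference) leaves the
        likelihood unchanged; pinning outcome 1 removes the degeneracy."""
        rng = np.random.default_rng(3)
        trials = [
            TrialOffer(i, random_option(rng), random_option(rng)) for i in range(1, 31)
        ]
        choices = rng.choice([-1, 1], size=30)
        matrix = TrialMatrix.build(trials, choices, 6)
        u = np.array([0.0, 1.0, -2.0, 3.0, 0.5, -1.0])
        shift = 1.5

        def nll_with_full_vector(u_full, alpha=3.0):
            from klchoice.fitting import _value_difference

            dv = _value_difference(matrix, u_full, kl_spec.valuation)
            z = alpha * matrix.choices * dv
            return float(np.sum(np.logaddexp(0.0, -z)))

        assert nll_with_full_vector(u) == pytest.approx(
            nll_with_full_vector(u + shift), abs=1e-9
        )


class TestRatingCorrelation:
    def _fit(self, profile):
        return SubjectFit(
            subject_id=1,
            spec=ModelSpec(),
            alpha_hat=4.0,
            utilities_hat=profile,
            log_likelihood=-100.0,
            n_params=6,
            bic_score=-117.0,
            n_trials=300,
        )

    def test_affine_image_gives_unit_correlation(self, profile):
        ratings = pd.DataFrame(
            {
                "outcome_id": list(range(1, 7)),
                "repeat": 1,
                "rating": 2.0 * profile.vector(6) + 3.0,
            }
        )
        assert rating_correlation(self._fit(profile), ratings) == pytest.approx(1.0)

    def test_reversed_affine_image_gives_minus_one(self, profile):
        ratings = pd.DataFrame(
            {
                "outcome_id": list(range(1, 7)),
                "repeat": 1,
                "rating": -profile.vector(6) + 1.0,
            }
        )
        assert rating_correlation(self._fit(profile), ratings) == pytest.approx(-1.0)

    def test_zero_variance_ratings_flagged_nan(self, profile):
        ratings = pd.DataFrame(
            {"outcome_id": list(range(1, 7)), "repeat": 1, "rating": 0.0}
        )
        with pytest.warns(RuntimeWarning):
            assert math.isnan(rating_correlation(self._fit(profile), ratings))

    def test_missing_outcomes_raise(self, profile):
        ratings = pd.DataFrame({"outcome_id": [1, 2], "repeat": 1, "rating": [0.0, 1.0]})
        with pytest.raises(ValueError):
            rating_correlation(self._fit(profile), ratings)

    def test_fitted_utilities_track_ratings_at_large_n(self, profile, kl_spec):
        """Consistency: with many trials and noise-free ratings equal to the
        true utilities, the fitted-vs-rated correlation approaches 1."""
        agent = AgentSpec(profile, PrecisionPrior(4.0), kl_spec, rating_noise_sd=0.0)
        trials = generate_design(DesignSpec(n_trials=1000), profile, seed=19)
        choices = simulate_choices(trials, agent, seed=20)
        fit = fit_subject(trials, choices, kl_spec, n_restarts=5, seed=8)
        ratings = emit_ratings(agent, seed=0)
        assert rating_correlation(fit, ratings) > 0.95
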