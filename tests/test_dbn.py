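"""Collapsed Dirichlet-Multinomial model: predictive probabilities and oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from metachange import (
    GLU_GAL,
    CountStatistics,
    EnumerationError,
    Hyperparameters,
    ModelSpec,
    NutrientSequence,
    collapsed_nutrient_prob,
    collapsed_switch_prob,
    exact_posterior_predictive,
    flat_markov_posterior_predictive,
    flat_predictive_sequence,
    sample_from_prior,
)
from metachange.dbn import collapsed_nutrient_row, collapsed_switch_row


def seq(*obs):
    return NutrientSequence(GLU_GAL, np.array(obs))


class TestCollapsedSwitchProb:
    def test_uniform_prior_zero_counts(self):
        stats = CountStatistics.zeros(2, 2)
        hyper = Hyperparameters(np.ones(2), np.ones(2), np.ones(2), alpha_s_self=1, alpha_s_other=1)
        for i, j in itertools.product(range(2), repeat=2):
            assert collapsed_switch_prob(stats, hyper, i, j) == pytest.approx(0.5)

    def test_sticky_prior_zero_counts(self):
        stats = CountStatistics.zeros(2, 2)
        hyper = Hyperparameters.default(2, 2)  # self=2, other=1
        assert collapsed_switch_prob(stats, hyper, 0, 0) == pytest.approx(2 / 3)
        assert collapsed_switch_prob(stats, hyper, 1, 0) == pytest.approx(1 / 3)

    def test_counts_shift_the_predictive(self):
        stats = CountStatistics.zeros(2, 2)
        stats.S[:] = [[3, 1], [0, 0]]
        hyper = Hyperparameters(np.ones(2), np.ones(2), np.ones(2), alpha_s_self=1, alpha_s_other=1)
        assert collapsed_switch_prob(stats, hyper, 0, 0) == pytest.approx(4 / 6)

    def test_rows_normalize(self):
        stats = CountStatistics.zeros(3, 2)
        stats.S[:] = np.arange(9).reshape(3, 3)
        hyper = Hyperparameters(np.ones(3), np.ones(2), np.ones(2))
        for i in range(3):
            assert collapsed_switch_row(stats, hyper, i).sum() == pytest.approx(1.0)


class TestCollapsedNutrientProb:
    def test_zero_counts_uniform(self):
        stats = CountStatistics.zeros(2, 2)
        hyper = Hyperparameters.default(2, 2)
        assert collapsed_nutrient_prob(stats, hyper, 0, 1, 0) == pytest.approx(0.5)

    def test_observed_transitions_shift_probability(self):
        stats = CountStatistics.zeros(2, 2)
        stats.C[0, 1, 1] = 2  # Glu -> Gal twice under switch state 1
        hyper = Hyperparameters.default(2, 2)
        assert collapsed_nutrient_prob(stats, hyper, 0, 1, 1) == pytest.approx(3 / 4)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_normalize_for_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        stats = CountStatistics(
            S=rng.integers(0, 20, (2, 2)), C=rng.integers(0, 20, (3, 3, 2))
        )
        hyper = Hyperparameters(np.ones(2), np.ones(3), rng.uniform(0.1, 3, 3))
        for c_prev, s in itertools.product(range(3), range(2)):
            assert collapsed_nutrient_row(stats, hyper, c_prev, s).sum() == pytest.approx(1.0)


class TestMonteCarloConjugacy:
    def test_collapsed_probability_equals_dirichlet_posterior_mean(self):
        # the collapsed ratio must match Monte-Carlo integration over the
        # Dirichlet posterior within 3 MC standard errors
        rng = np.random.default_rng(2024)
        n_mc = 40_000
        for _ in range(10):
            J = rng.integers(2, 4)
            alpha = rng.uniform(0.5, 3.0, J)
            counts = rng.integers(0, 15, J)
            hyper = Hyperparameters(np.ones(2), np.ones(J), alpha)
            stats = CountStatistics.zeros(2, J)
            stats.C[0, :, 0] = counts
            draws = rng.dirichlet(alpha + counts, size=n_mc)
            for j in range(J):
                mc_mean = draws[:, j].mean()
                mc_se = draws[:, j].std(ddof=1) / np.sqrt(n_mc)
                exact = collapsed_nutrient_prob(stats, hyper, 0, j, 0)
                assert abs(exact - mc_mean) < 3 * mc_se


class TestSampleFromPrior:
    def test_reproducible(self):
        spec = ModelSpec(K=2, J=2)
        a = sample_from_prior(spec, 50, seed=3)
        b = sample_from_prior(spec, 50, seed=3)
        np.testing.assert_array_equal(a.observations, b.observations)
        np.testing.assert_array_equal(a.true_switch_states, b.true_switch_states)

    def test_symmetric_prior_initial_nutrient_is_uniform(self):
        spec = ModelSpec(K=1, J=2)
        first = [sample_from_prior(spec, 1, seed=s).observations[0] for s in range(400)]
        frac = np.mean(np.array(first) == 0)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 400)

    def test_long_trace_frequencies_match_drawn_parameters(self):
        # with K=1 the trace is a Markov chain with the drawn matrix; its
        # empirical transition frequencies must agree within binomial error
        spec = ModelSpec(K=1, J=2)
        trace = sample_from_prior(spec, 5000, seed=9)
        obs = trace.observations
        # recover the drawn matrix by replaying the rng draws
        rng = np.random.default_rng(9)
        rng.dirichlet(spec.hyper.alpha_s1)
        rng.dirichlet(spec.hyper.switch_alpha(1)[0])
        rng.dirichlet(spec.hyper.alpha_c0)
        pi_c = np.stack([[rng.dirichlet(spec.hyper.alpha_c) for _ in range(1)] for _ in range(2)])
        for i in range(2):
            mask = obs[:-1] == i
            n = mask.sum()
            frac = (obs[1:][mask] == 0).mean()
            p = pi_c[i, 0, 0]
            assert abs(frac - p) < 4 * np.sqrt(max(p * (1 - p), 1e-4) / n)


def _independent_enumeration(history, spec):
    """Brute-force posterior predictive via closed-form marginal likelihoods.

    Enumerates every full assignment of hidden states s_{1:T+1} and the
    next nutrient, scoring each with the Dirichlet-Multinomial marginal
    likelihood written in terms of log-gamma functions (a batch closed
    form, independent of the sequential-ratio implementation under test).
    """
    obs = history.observations
    T = len(obs) - 1
    K, J, hyper = spec.K, spec.J, spec.hyper
    alpha_s1 = hyper.alpha_s1 / hyper.alpha_s1.sum()
    switch_alpha = hyper.switch_alpha(K)

    def row_marginal(alpha_row, count_row):
        return (
            gammaln(alpha_row.sum())
            - gammaln(alpha_row.sum() + count_row.sum())
            + np.sum(gammaln(alpha_row + count_row) - gammaln(alpha_row))
        )

    scores = np.full(J, -np.inf)
    for s_traj in itertools.product(range(K), repeat=T + 1):
        for c_next in range(J):
            cs = np.concatenate([obs, [c_next]])
            s_counts = np.zeros((K, K))
            for a, b in zip(s_traj[:-1], s_traj[1:]):
                s_counts[a, b] += 1
            c_counts = np.zeros((J, J, K))
            for t in range(1, T + 2):
                c_counts[cs[t - 1], cs[t], s_traj[t - 1]] += 1
            logp = np.log(alpha_s1[s_traj[0]])
            for i in range(K):
                logp += row_marginal(switch_alpha[i], s_counts[i])
            for i, k in itertools.product(range(J), range(K)):
                logp += row_marginal(hyper.alpha_c, c_counts[i, :, k])
            scores[c_next] = np.logaddexp(scores[c_next], logp)
    probs = np.exp(scores - scores.max())
    return probs / probs.sum()


class TestExactPosteriorPredictive:
    def test_prior_predictive_is_uniform(self):
        spec = ModelSpec(K=2, J=2)
        np.testing.assert_allclose(exact_posterior_predictive(seq(0), spec), [0.5, 0.5])

    def test_single_observation_no_counts_yet(self):
        spec = ModelSpec(K=1, J=2)
        np.testing.assert_allclose(exact_posterior_predictive(seq(0), spec), [0.5, 0.5])

    @pytest.mark.parametrize(
        "obs",
        [(0, 1, 0, 1), (0, 0, 0), (0, 1, 1, 0), (1, 0, 0, 1, 0)],
    )
    def test_matches_independent_closed_form_enumeration(self, obs):
        spec = ModelSpec(K=2, J=2)  # sticky switch prior by default
        mine = exact_posterior_predictive(seq(*obs), spec)
        brute = _independent_enumeration(seq(*obs), spec)
        np.testing.assert_allclose(mine, brute, atol=1e-10)

    def test_k1_equals_flat_markov_model(self):
        spec = ModelSpec(K=1, J=2)
        for obs in [(0, 0, 1, 0), (0, 1, 1, 1, 0), (1, 0)]:
            np.testing.assert_allclose(
                exact_posterior_predictive(seq(*obs), spec),
                flat_markov_posterior_predictive(seq(*obs), np.ones(2)),
                atol=1e-12,
            )

    def test_label_permutation_symmetry(self):
        # swapping nutrient labels everywhere permutes the prediction
        spec = ModelSpec(K=2, J=2)
        obs = (0, 1, 1, 0, 1)
        swapped = tuple(1 - c for c in obs)
        p = exact_posterior_predictive(seq(*obs), spec)
        q = exact_posterior_predictive(seq(*swapped), spec)
        np.testing.assert_allclose(p, q[::-1], atol=1e-12)

    def test_three_nutrient_prediction_normalizes(self):
        from metachange import GLU_GAL_MAL

        spec = ModelSpec(K=2, J=3)
        three = NutrientSequence(GLU_GAL_MAL, np.array([0, 1, 2, 1, 0]))
        p = exact_posterior_predictive(three, spec)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)

    def test_infeasible_horizon_raises(self):
        spec = ModelSpec(K=2, J=2)
        long_seq = seq(*([0, 1] * 10))
        with pytest.raises(EnumerationError, match="infeasible"):
            exact_posterior_predictive(long_seq, spec)


class TestFlatMarkovModel:
    def test_no_transitions_from_current_state_is_uniform(self):
        np.testing.assert_allclose(flat_markov_posterior_predictive(seq(0), np.ones(2)), [0.5, 0.5])

    def test_hand_counted_history(self):
        # history Glu,Glu,Gal,Glu: from Glu once to Glu, once to Gal
        p = flat_markov_posterior_predictive(seq(0, 0, 1, 0), np.ones(2))
        assert p[0] == pytest.approx((1 + 1) / (2 + 2))

    def test_constant_history_closed_form_and_monotonicity(self):
        prev = 0.0
        for n in range(1, 12):
            p = flat_markov_posterior_predictive(seq(*([0] * (n + 1))), np.ones(2))
            assert p[0] == pytest.approx((1 + n) / (2 + n))
            assert p[0] > prev
            prev = p[0]

    def test_predictive_sequence_rows_are_pre_observation(self):
        preds = flat_predictive_sequence(seq(0, 0, 0, 1), np.ones(2))
        np.testing.assert_allclose(preds[0], [0.5, 0.5])  # nothing seen yet
        np.testing.assert_allclose(preds[1], [2 / 3, 1 / 3])
        np.testing.assert_allclose(preds[2], [3 / 4, 1 / 4])
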