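"""Transition matrices, interval probabilities, episode likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest

from healthexpect.markov import (
    ModelError,
    MultistateLogitModel,
    StepParams,
    TransitionCoefficients,
    episode_loglik,
    interval_probability,
    one_year_table,
    step_matrix,
)
from conftest import episodes_frame, homogeneous_coeffs


class TestStepMatrix:
    def test_zero_coefficients_give_uniform_row(self):
        c = homogeneous_coeffs((0.0, 0.0, 0.0, 0.0))
        m = step_matrix(c, 80.0)
        assert np.allclose(m.probs[0], [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(m.probs[1], [1 / 3, 1 / 3, 1 / 3])

    def test_death_is_absorbing(self):
        c = homogeneous_coeffs()
        for age in (65.0, 80.0, 99.0):
            assert np.array_equal(step_matrix(c, age).probs[2], [0.0, 0.0, 1.0])

    def test_large_negative_logits_pin_the_diagonal(self):
        c = homogeneous_coeffs((-50.0, -50.0, -50.0, -50.0))
        m = step_matrix(c, 80.0)
        assert m.probs[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert m.probs[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_rows_are_stochastic(self):
        rng = np.random.default_rng(5)
        c = TransitionCoefficients(
            coef=rng.normal(-1, 1, (4, 2)), covariates=(), step=StepParams(h=0.25)
        )
        for age in np.linspace(65, 109, 12):
            assert np.allclose(step_matrix(c, age).probs.sum(axis=1), 1.0, atol=1e-12)

    def test_undeclared_profile_rejected(self):
        c = homogeneous_coeffs()
        with pytest.raises(ModelError):
            step_matrix(c, 80.0, {"lonely": 1})


class TestIntervalProbability:
    def test_single_step_equals_step_matrix(self):
        c = homogeneous_coeffs(h=1.0)
        assert np.allclose(
            interval_probability(c, 80.0, 1.0).probs, step_matrix(c, 80.0).probs
        )

    def test_homogeneous_two_steps_is_matrix_square(self):
        c = homogeneous_coeffs(h=1.0)
        P = step_matrix(c, 80.0).probs
        assert np.allclose(interval_probability(c, 80.0, 2.0).probs, P @ P, atol=1e-14)

    def test_36_step_product_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        coef = rng.normal(-2, 0.7, (4, 2))
        h = 1.0 / 12.0
        c = TransitionCoefficients(coef=coef, covariates=(), step=StepParams(h=h))
        got = interval_probability(c, 70.0, 3.0).probs

        # independent left-to-right product from the logit definition
        expected = np.eye(3)
        for u in range(36):
            age = 70.0 + u * h
            z = np.array([1.0, age - 80.0])
            eta = coef @ z
            e = np.exp(eta)
            P = np.zeros((3, 3))
            P[0] = np.array([1.0, e[0], e[1]]) / (1 + e[0] + e[1])
            P[1] = np.array([e[2], 1.0, e[3]]) / (1 + e[2] + e[3])
            P[2, 2] = 1.0
            expected = expected @ P
        assert np.allclose(got, expected, atol=1e-12)

    def test_truncation_beyond_cap_rejected(self):
        c = homogeneous_coeffs(h=1.0)
        with pytest.raises(ModelError, match="cap"):
            interval_probability(c, 105.0, 10.0)


class TestEpisodeLoglik:
    def test_single_transition_log_probability(self):
        # p(1->2) = 0.3 in one annual step; death channel switched off
        a12 = np.log(0.3 / 0.7)
        c = homogeneous_coeffs((a12, -50.0, -1.0, -50.0), h=1.0)
        ep = episodes_frame([(80.0, 1, 1.0, 2)])
        assert episode_loglik(c, ep) == pytest.approx(np.log(0.3), abs=1e-9)

    def test_death_one_step_after_observation(self):
        c = homogeneous_coeffs(h=1.0)
        p13 = step_matrix(c, 80.0).probs[0, 2]
        ep = episodes_frame([(80.0, 1, 1.0, 3)])
        assert episode_loglik(c, ep) == pytest.approx(np.log(p13))

    def test_three_individual_fixture_matches_hand_sum(self):
        c = homogeneous_coeffs(h=1.0)
        P = step_matrix(c, 80.0).probs
        eps = episodes_frame(
            [
                (80.0, 1, 2.0, 2),  # two-step transition to unhealthy
                (80.0, 2, 1.0, 1),  # one-step recovery
                (80.0, 1, 2.0, 3),  # survive one step among living, die in second
            ]
        )
        P2 = P @ P
        hand = (
            np.log(P2[0, 1])
            + np.log(P[1, 0])
            + np.log(P[0, 0] * P[0, 2] + P[0, 1] * P[1, 2])
        )
        assert episode_loglik(c, eps) == pytest.approx(hand, abs=1e-10)

    def test_impossible_episode_is_minus_infinity(self):
        # near-certain death each step makes 16 years of survival in state 1
        # numerically impossible (probability underflows to zero)
        c = homogeneous_coeffs((-50.0, 50.0, -50.0, 50.0), h=1.0)
        ep = episodes_frame([(80.0, 1, 16.0, 1)])
        with pytest.warns(UserWarning, match="zero-probability"):
            assert episode_loglik(c, ep) == -np.inf


def _multinomial_episodes(counts, weights=1.0):
    """Fully observed single-interval data: counts[j][k] episodes j->k."""
    rows = []
    for j, row in counts.items():
        for k, n in row.items():
            rows.extend((80.0, j, 1.0, k) for _ in range(n))
    eps = episodes_frame(rows)
    eps["weight"] = weights
    return eps


class TestFit:
    def test_empty_episode_set_rejected(self):
        with pytest.raises(ModelError):
            MultistateLogitModel(h=1.0, covariates=()).fit(pd.DataFrame())

    def test_intercept_only_fit_matches_multinomial_frequencies(self):
        counts = {1: {1: 50, 2: 30, 3: 20}, 2: {1: 10, 2: 25, 3: 15}}
        eps = _multinomial_episodes(counts)
        model = MultistateLogitModel(h=1.0, covariates=(), age_slope=False, gtol=1e-9)
        model.fit(eps)
        P = interval_probability(model.coefficients_, 80.0, 1.0).probs
        assert np.allclose(P[0], [0.5, 0.3, 0.2], atol=1e-6)
        assert np.allclose(P[1], [0.2, 0.5, 0.3], atol=1e-6)

    def test_weighted_fit_matches_weighted_frequencies(self):
        counts = {1: {1: 40, 2: 20, 3: 10}, 2: {1: 8, 2: 30, 3: 12}}
        eps = _multinomial_episodes(counts)
        w = np.where(np.arange(len(eps)) % 2 == 0, 2.0, 0.5)
        eps["weight"] = w
        model = MultistateLogitModel(h=1.0, covariates=(), age_slope=False, gtol=1e-9)
        model.fit(eps)
        P = interval_probability(model.coefficients_, 80.0, 1.0).probs
        for j in (1, 2):
            sub = eps[eps.state_start == j]
            tot = sub["weight"].sum()
            for k in (1, 2, 3):
                want = sub.loc[sub.end_state == k, "weight"].sum() / tot
                assert P[j - 1, k - 1] == pytest.approx(want, abs=1e-6)

    def test_weight_rescaling_leaves_estimates_unchanged(self):
        counts = {1: {1: 30, 2: 10, 3: 5}, 2: {1: 5, 2: 20, 3: 10}}
        m1 = MultistateLogitModel(h=1.0, covariates=(), age_slope=False)
        m1.fit(_multinomial_episodes(counts, weights=1.0))
        m2 = MultistateLogitModel(h=1.0, covariates=(), age_slope=False)
        m2.fit(_multinomial_episodes(counts, weights=3.0))
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-6)

    def test_invariance_to_id_relabeling_and_row_order(self, small_cohort):
        _, truth = small_cohort
        eps = truth["episodes_adl"]
        m1 = MultistateLogitModel(h=0.25, covariates=("lonely",))
        m1.fit(eps)
        shuffled = eps.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["id"] = shuffled["id"].map(lambda i: f"ind_{i}")
        m2 = MultistateLogitModel(h=0.25, covariates=("lonely",))
        m2.fit(shuffled)
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-5)

    def test_fitted_loglik_at_least_truth_loglik(self, small_cohort, true_model_quarter):
        _, truth = small_cohort
        eps = truth["episodes_adl"]
        model = MultistateLogitModel(h=0.25, covariates=("lonely",))
        model.fit(eps)
        ll_true = model.score_params(true_model_quarter.health.coef, eps)
        assert model.loglik_ >= ll_true - 1e-6


class TestOneYearTable:
    def test_annual_step_table_equals_step_matrix(self):
        c = homogeneous_coeffs(h=1.0)
        tab = one_year_table(c, [80.0], n_draws=0)
        P = step_matrix(c, 80.0).probs
        for _, r in tab.iterrows():
            assert r["estimate"] == pytest.approx(P[int(r["origin"]) - 1, int(r["destination"]) - 1])

    def test_rows_sum_to_one_at_all_ages(self, fitted_model):
        coeffs = fitted_model.coefficients_
        tab = one_year_table(coeffs, [65, 75, 85, 95], {"lonely": 0}, n_draws=0)
        sums = tab.groupby(["age", "origin"])["estimate"].sum()
        assert np.allclose(sums, 1.0, atol=1e-10)

    def test_planted_loneliness_raises_death_probability(self, fitted_model):
        coeffs = fitted_model.coefficients_
        for age in (65, 75, 85):
            t0 = one_year_table(coeffs, [age], {"lonely": 0}, n_draws=0)
            t1 = one_year_table(coeffs, [age], {"lonely": 1}, n_draws=0)
            p0 = t0[(t0.origin == 1) & (t0.destination == 3)]["estimate"].iloc[0]
            p1 = t1[(t1.origin == 1) & (t1.destination == 3)]["estimate"].iloc[0]
            assert p1 > p0

    def test_bootstrap_ses_are_seeded(self, fitted_model):
        coeffs = fitted_model.coefficients_
        t1 = one_year_table(coeffs, [75.0], {"lonely": 0}, n_draws=150, seed=5)
        t2 = one_year_table(coeffs, [75.0], {"lonely": 0}, n_draws=150, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["se"].dropna() >= 0).all()


class TestMarginalDeath:
    def test_unknown_death_date_uses_dead_column_mass(self):
        from healthexpect.markov import interval_probability
        from conftest import homogeneous_coeffs, episodes_frame

        c = homogeneous_coeffs(h=1.0)
        ep = episodes_frame([(80.0, 1, 3.0, 3)])
        ep["death_age"] = np.nan  # death known only to precede the contact
        want = np.log(interval_probability(c, 80.0, 3.0).probs[0, 2])
        from healthexpect.markov import episode_loglik
        assert episode_loglik(c, ep) == pytest.approx(want, abs=1e-12)

    def test_interval_censored_generator_mode_fits(self):
        from healthexpect.simulate import SimulationConfig, generate_cohort, recovery_true_model
        from healthexpect.coding import CodingRules, build_histories, recode_cohort

        tm = recovery_true_model(0.25)
        cfg = SimulationConfig(n=800, seed=21, true_model=tm, exact_death_dates=False)
        cohort, truth = generate_cohort(cfg)
        assert cohort["death_age"].isna().all()
        assert cohort["death_report_age"].notna().any()
        rec = recode_cohort(cohort, CodingRules(indicator="adl"))
        _, eps = build_histories(rec)
        te = truth["episodes_adl"]
        assert len(eps) == len(te)
        assert eps[eps.end_state == 3]["death_age"].isna().all()
        model = MultistateLogitModel(h=0.25, covariates=("lonely",))
        model.fit(eps)
        assert model.converged_
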