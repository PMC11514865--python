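"""Stable prevalence, expectancies, bootstrap CIs and the Kannisto fit."""

import numpy as np
import pytest

from healthexpect.lifetable import (
    conditional_expectancies,
    confidence_intervals,
    kannisto_fit,
    population_expectancies,
    stable_prevalence,
)
from healthexpect.markov import ModelError, StepParams, TransitionCoefficients, step_matrix
from conftest import homogeneous_coeffs


class TestStablePrevalence:
    def test_symmetric_chain_splits_evenly(self):
        c = homogeneous_coeffs((-2.0, -3.0, -2.0, -3.0))
        pv = stable_prevalence(c, 80.0, burn_in=400.0, tol=1e-10)
        assert pv.w1 == pytest.approx(0.5, abs=1e-9)
        assert pv.w2 == pytest.approx(0.5, abs=1e-9)

    def test_absorbing_living_state_dominates(self):
        # no recovery, no mortality: everyone ends unhealthy
        c = homogeneous_coeffs((-2.0, -50.0, -50.0, -50.0))
        pv = stable_prevalence(c, 80.0, burn_in=300.0, tol=1e-10)
        assert pv.w2 == pytest.approx(1.0, abs=1e-6)

    def test_matches_dominant_left_eigenvector(self):
        c = homogeneous_coeffs((-2.0, -3.0, -1.5, -2.5))
        Q = step_matrix(c, 80.0).probs[:2, :2]
        vals, vecs = np.linalg.eig(Q.T)
        w = vecs[:, np.argmax(vals.real)].real
        w = w / w.sum()
        pv = stable_prevalence(c, 80.0, burn_in=500.0, tol=1e-12)
        assert abs(pv.w1 - w[0]) < 1e-8

    def test_burn_in_reported(self):
        c = homogeneous_coeffs((-1.0, -2.0, -1.0, -2.0))
        pv = stable_prevalence(c, 90.0, burn_in=200.0, tol=1e-8)
        assert 0 < pv.burn_in <= 200.0
        assert pv.converged


class TestConditionalExpectancies:
    def test_fundamental_matrix_oracle(self):
        c = homogeneous_coeffs((-2.0, -3.0, -1.5, -2.5), h=1.0, age_cap=5000.0)
        Q = step_matrix(c, 80.0).probs[:2, :2]
        oracle = np.linalg.inv(np.eye(2) - Q) - 0.5 * np.eye(2)
        e = conditional_expectancies(c, 80.0)
        assert np.abs(e - oracle).max() < 1e-6

    def test_immediate_certain_death_leaves_half_step(self):
        c = homogeneous_coeffs((-50.0, 50.0, -50.0, 50.0), h=0.25)
        e = conditional_expectancies(c, 80.0)
        assert e[0, 0] == pytest.approx(0.125, abs=1e-8)
        assert e[1, 1] == pytest.approx(0.125, abs=1e-8)
        assert abs(e[0, 1]) < 1e-8 and abs(e[1, 0]) < 1e-8

    def test_geometric_closed_form_without_transitions(self):
        q = 0.2  # annual death probability, no movement between living states
        a13 = np.log(q / (1 - q))
        c = homogeneous_coeffs((-50.0, a13, -50.0, a13), h=1.0, age_cap=5000.0)
        e = conditional_expectancies(c, 80.0)
        # survival is geometric: e11 = 1/2 + sum_u (1-q)^u = 1/2 + (1-q)/q
        assert e[0, 0] == pytest.approx(0.5 + (1 - q) / q, abs=1e-6)

    def test_halving_h_changes_le_less_than_half_step(self):
        # one continuous-time chain, discretized exactly at two step lengths
        # (any fixed stochastic matrix is representable by intercept-only logits)
        from scipy.linalg import expm

        G = np.array([[-0.30, 0.20, 0.10], [0.25, -0.45, 0.20], [0.0, 0.0, 0.0]])
        les = {}
        for h in (0.25, 0.125):
            P = expm(G * h)
            a = np.log([P[0, 1] / P[0, 0], P[0, 2] / P[0, 0],
                        P[1, 0] / P[1, 1], P[1, 2] / P[1, 1]])
            c = homogeneous_coeffs(a, h=h, age_cap=5000.0)
            e = conditional_expectancies(c, 80.0)
            les[h] = e[0, 0] + e[0, 1]  # remaining life from the healthy state
        assert abs(les[0.25] - les[0.125]) < 0.125


class TestPopulationExpectancies:
    def test_degenerate_mixture_reduces_to_conditional_row(self):
        # recovery-free chain with no morbidity: stable prevalence is all-healthy
        c = homogeneous_coeffs((-50.0, -2.0, -1.0, -2.0))
        res = population_expectancies(c, 80.0, burn_in=300.0, tol=1e-12)
        e = conditional_expectancies(c, 80.0)
        assert res.w2 == pytest.approx(0.0, abs=1e-9)
        assert res.hle == pytest.approx(e[0, 0], rel=1e-9)

    def test_additivity_is_exact(self, fitted_model):
        coeffs = fitted_model.coefficients_
        for age in (65.0, 75.0, 85.0, 95.0):
            for lon in (0, 1):
                r = population_expectancies(coeffs, age, {"lonely": lon})
                assert r.le == r.hle + r.ule  # exact float identity

    def test_all_healthy_time_gives_ratio_100(self):
        c = homogeneous_coeffs((-50.0, -2.0, -1.0, -50.0))
        res = population_expectancies(c, 80.0, burn_in=300.0, tol=1e-12)
        assert res.hle_pct == pytest.approx(100.0, abs=1e-6)

    def test_le_decreases_with_age(self, fitted_model):
        coeffs = fitted_model.coefficients_
        les = [population_expectancies(coeffs, a, {"lonely": 0}).le for a in (65, 75, 85, 95)]
        assert all(b < a for a, b in zip(les, les[1:]))


class TestConfidenceIntervals:
    def _coeffs_with_cov(self, scale=1.0):
        c = homogeneous_coeffs((-2.5, -3.5, -1.5, -3.0), h=1.0)
        cov = scale * 0.005 * np.eye(4)
        return TransitionCoefficients(
            coef=c.coef, covariates=(), step=c.step, age_slope=False, cov=cov
        )

    def test_zero_covariance_collapses_to_point(self):
        c = self._coeffs_with_cov(scale=0.0)
        ci = confidence_intervals(c, [80.0], n_draws=150, seed=1)
        assert np.allclose(ci["lower"], ci["estimate"], atol=1e-9)
        assert np.allclose(ci["upper"], ci["estimate"], atol=1e-9)

    def test_same_seed_reproduces(self):
        c = self._coeffs_with_cov()
        ci1 = confidence_intervals(c, [80.0], n_draws=200, seed=7)
        ci2 = confidence_intervals(c, [80.0], n_draws=200, seed=7)
        assert ci1.equals(ci2)

    def test_quadrupled_variance_doubles_width(self):
        ci1 = confidence_intervals(self._coeffs_with_cov(1.0), [80.0], n_draws=800, seed=3)
        ci4 = confidence_intervals(self._coeffs_with_cov(4.0), [80.0], n_draws=800, seed=3)
        for qty in ("le", "hle"):
            w1 = ci1[ci1.quantity == qty].iloc[0]
            w4 = ci4[ci4.quantity == qty].iloc[0]
            ratio = (w4["upper"] - w4["lower"]) / (w1["upper"] - w1["lower"])
            assert 1.6 < ratio < 2.4

    def test_non_psd_covariance_rejected(self):
        c = self._coeffs_with_cov()
        bad = TransitionCoefficients(
            coef=c.coef, covariates=(), step=c.step, age_slope=False,
            cov=np.diag([1.0, 1.0, 1.0, -1.0]),
        )
        with pytest.raises(ModelError):
            confidence_intervals(bad, [80.0], n_draws=150, seed=0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ModelError):
            confidence_intervals(self._coeffs_with_cov(), [80.0], n_draws=50)


class TestKannisto:
    def test_exact_rates_recovered(self):
        ages = np.arange(65.0, 100.0, 5.0)
        a, b = 0.01, 0.1
        z = a * np.exp(b * (ages - 65.0))
        q = z / (1 + z)
        expo = np.full_like(ages, 10000.0)
        fit = kannisto_fit(ages, expo * q, expo)
        assert abs(fit.a - a) < 1e-3
        assert abs(fit.b - b) < 1e-3

    def test_flat_rates_give_zero_slope(self):
        ages = np.arange(65.0, 100.0, 5.0)
        expo = np.full_like(ages, 5000.0)
        fit = kannisto_fit(ages, expo * 0.05, expo)
        assert abs(fit.b) < 1e-4

    def test_hazard_bounded_below_one(self):
        ages = np.arange(65.0, 100.0, 5.0)
        z = 0.02 * np.exp(0.12 * (ages - 65.0))
        expo = np.full_like(ages, 1000.0)
        fit = kannisto_fit(ages, expo * z / (1 + z), expo)
        assert fit.hazard(150.0) < 1.0

    def test_needs_four_age_groups(self):
        with pytest.raises(ModelError):
            kannisto_fit(np.array([65.0, 70, 75]), np.array([1.0, 2, 3]), np.array([10.0, 10, 10]))
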