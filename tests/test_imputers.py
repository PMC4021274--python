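"""Imputer tests: posterior-draw calibration, truncated-normal sampler and
ML fit against closed forms and scipy oracles, PMM donor rules, clamping
accounting, and the multiple-imputation orchestration invariants."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import kstest, truncnorm

from boundedmi import (ImputationError, design_matrix, draw_bayes_linreg,
                       fit_truncreg_ml, impute_pmm, impute_regress,
                       impute_truncreg, multiple_impute, round_to_bounds,
                       sample_truncnorm)
from boundedmi.imputers import trunc_nll, trunc_nll_grad


def linear_data(rng, n=2000, beta=(1.0, 2.0, -1.0), sigma=1.5):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = X @ np.asarray(beta) + sigma * rng.standard_normal(n)
    return y, X, np.asarray(beta), sigma


class TestBayesDraw:
    def test_draws_concentrate_on_generating_coefficients(self, rng):
        y, X, beta, sigma = linear_data(rng)
        draws = np.array([draw_bayes_linreg(y, X, rng).beta_star
                          for _ in range(1000)])
        se = sigma / np.sqrt(len(y))  # asymptotic scale of each coefficient
        assert np.all(np.abs(draws.mean(0) - beta) < 3 * se)

    def test_fixed_seed_reproduces_the_draw(self, rng):
        y, X, *_ = linear_data(rng, n=100)
        d1 = draw_bayes_linreg(y, X, np.random.default_rng(5))
        d2 = draw_bayes_linreg(y, X, np.random.default_rng(5))
        np.testing.assert_array_equal(d1.beta_star, d2.beta_star)
        assert d1.sigma_star == d2.sigma_star

    def test_exact_linear_fit_is_degenerate(self, rng):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        y = X @ np.array([1.0, 2.0])
        with pytest.raises(ImputationError, match="residual"):
            draw_bayes_linreg(y, X, rng)

    def test_rank_deficiency_is_rejected(self, rng):
        X = np.column_stack([np.ones(50), np.ones(50)])
        y = rng.standard_normal(50)
        with pytest.raises(ImputationError, match="rank"):
            draw_bayes_linreg(y, X, rng)


class TestImputeRegress:
    def test_no_missingness_returns_input(self, rng):
        y, X, *_ = linear_data(rng, n=100)
        mask = np.zeros(100, dtype=bool)
        np.testing.assert_array_equal(impute_regress(y, X, mask, rng), y)

    def test_severe_skew_imputes_below_lower_bound(self, severe_data,
                                                   mcar_mask, rng):
        X = design_matrix(severe_data.outcome, severe_data.aux)
        y = impute_regress(severe_data.score[~mcar_mask], X, mcar_mask, rng)
        assert (y[mcar_mask] < severe_data.lo).mean() > 0.02


class TestRoundToBounds:
    def test_clamps_and_keeps_boundaries(self):
        y = np.array([-2.3, 0.0, 5.0, 36.0, 40.1])
        np.testing.assert_array_equal(round_to_bounds(y, 0, 36),
                                      [0.0, 0.0, 5.0, 36.0, 36.0])

    def test_changed_count_equals_out_of_range_count(self, rng):
        y = rng.normal(0, 10, size=500)
        clamped = round_to_bounds(y, 0, 12)
        assert np.sum(clamped != y) == np.sum((y < 0) | (y > 12))

    def test_requires_ordered_bounds(self):
        with pytest.raises(ValueError):
            round_to_bounds(np.array([1.0]), 5, 5)


class TestTruncatedSampler:
    def test_mean_matches_closed_form_and_quadrature(self, rng):
        draws = sample_truncnorm(np.zeros(100_000), 1.0, 0.0, 12.0, rng)
        closed = 0.7978845608  # (phi(0) - phi(12)) / (Phi(12) - Phi(0))
        numeric = integrate.quad(
            lambda y: y * np.exp(-y * y / 2) / np.sqrt(2 * np.pi) / 0.5,
            0, 12)[0]
        assert closed == pytest.approx(numeric, abs=1e-9)
        mc_se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - closed) < 3 * mc_se

    def test_draws_respect_bounds(self, rng):
        draws = sample_truncnorm(np.full(10_000, 5.0), 4.0, 0.0, 12.0, rng)
        assert draws.min() >= 0.0 and draws.max() <= 12.0

    def test_distribution_matches_scipy_truncnorm(self, rng):
        mu, sigma, lo, hi = 3.0, 2.0, 0.0, 12.0
        draws = sample_truncnorm(np.full(20_000, mu), sigma, lo, hi, rng)
        dist = truncnorm((lo - mu) / sigma, (hi - mu) / sigma, mu, sigma)
        assert kstest(draws, dist.cdf).pvalue > 0.01

    def test_underflowing_mass_errors(self, rng):
        with pytest.raises(ImputationError, match="underflow"):
            sample_truncnorm(np.array([-1000.0]), 1.0, 0.0, 12.0, rng)


class TestTruncregFit:
    def test_untruncated_limit_equals_least_squares(self, rng):
        y, X, *_ = linear_data(rng, n=800)
        fit = fit_truncreg_ml(y, X, -np.inf, np.inf)
        beta_ls = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ls, atol=1e-6)
        sigma_ml = np.sqrt(np.mean((y - X @ beta_ls) ** 2))
        assert fit.sigma == pytest.approx(sigma_ml, abs=1e-6)

    def test_parameter_recovery_on_self_generated_truncated_data(self, rng):
        n, lo, hi = 4000, 0.0, 12.0
        beta, sigma = np.array([3.0, 1.5]), 3.0
        X = np.column_stack([np.ones(n), rng.random(n)])
        mu = X @ beta
        y = truncnorm.rvs((lo - mu) / sigma, (hi - mu) / sigma, mu, sigma,
                          random_state=rng)
        fit = fit_truncreg_ml(y, X, lo, hi)
        ses = np.sqrt(np.diag(fit.cov))
        assert np.all(np.abs(fit.beta - beta) < 3 * ses[:2])
        assert abs(np.log(fit.sigma) - np.log(sigma)) < 3 * ses[2]

    def test_gradient_vanishes_at_reported_optimum(self, rng):
        n, lo, hi = 1500, 0.0, 12.0
        beta, sigma = np.array([4.0, 2.0]), 2.5
        X = np.column_stack([np.ones(n), rng.random(n)])
        mu = X @ beta
        y = truncnorm.rvs((lo - mu) / sigma, (hi - mu) / sigma, mu, sigma,
                          random_state=rng)
        fit = fit_truncreg_ml(y, X, lo, hi)
        theta = np.append(fit.beta, np.log(fit.sigma))
        assert np.abs(trunc_nll_grad(theta, y, X, lo, hi)).max() < 1e-4

    def test_analytic_gradient_matches_finite_differences(self, rng):
        y, X, *_ = linear_data(rng, n=300)
        y = np.clip(y, -4, 8)
        theta = np.array([0.5, 1.0, -0.5, 0.3])
        from scipy.optimize import approx_fprime
        num = approx_fprime(theta, trunc_nll, 1e-7, y, X, -4.0, 8.0)
        ana = trunc_nll_grad(theta, y, X, -4.0, 8.0)
        np.testing.assert_allclose(ana, num, rtol=1e-4, atol=1e-3)

    def test_imputations_fall_inside_bounds(self, severe_data, mcar_mask,
                                            rng):
        X = design_matrix(severe_data.outcome, severe_data.aux)
        fit = fit_truncreg_ml(severe_data.score[~mcar_mask], X[~mcar_mask],
                              severe_data.lo, severe_data.hi)
        y = impute_truncreg(fit, X, mcar_mask, rng)
        filled = y[mcar_mask]
        assert filled.min() >= severe_data.lo
        assert filled.max() <= severe_data.hi


class TestPMM:
    def test_toy_candidate_set_and_donor_frequencies(self):
        # observed y = (1, 2, 10) with predictions equal to the values and
        # one missing case predicted at 1.4: with k=2 the candidate donors
        # are {1, 2}, each picked about half the time
        y_obs = np.array([1.0, 2.0, 10.0])
        X = np.array([[1.0], [2.0], [10.0], [1.4]])
        mask = np.array([False, False, False, True])
        draws = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            # slope-only design: beta_hat == 1 exactly, so yhat == X
            got = impute_pmm(y_obs, X, mask, rng, k=2, matching="type0")
            draws.append(got[3])
        counts = {v: draws.count(v) for v in set(draws)}
        assert set(counts) == {1.0, 2.0}
        assert 0.4 < counts[1.0] / 400 < 0.6

    def test_k1_takes_the_unique_nearest_donor(self):
        y_obs = np.array([1.0, 2.0, 10.0])
        X = np.array([[1.0], [2.0], [10.0], [1.4]])
        mask = np.array([False, False, False, True])
        for seed in range(20):
            got = impute_pmm(y_obs, X, mask, np.random.default_rng(seed),
                             k=1, matching="type0")
            assert got[3] == 1.0

    def test_all_imputed_values_are_observed_values(self, severe_data,
                                                    mcar_mask, rng):
        X = design_matrix(severe_data.outcome, severe_data.aux)
        y = impute_pmm(severe_data.score[~mcar_mask], X, mcar_mask, rng)
        assert np.isin(y[mcar_mask], severe_data.score[~mcar_mask]).all()

    def test_k_larger_than_donor_pool_errors(self, rng):
        y_obs = np.array([1.0, 2.0, 3.0])
        X = np.ones((4, 1))
        mask = np.array([False, False, False, True])
        with pytest.raises(ImputationError, match="k="):
            impute_pmm(y_obs, X, mask, rng, k=5)


class TestMultipleImpute:
    @pytest.mark.parametrize("method", ["regress", "regress_round",
                                        "truncreg", "pmm"])
    def test_observed_entries_identical_across_copies(self, severe_data,
                                                      mcar_mask, method):
        cset = multiple_impute(severe_data, mcar_mask, method, m=3, rng=1)
        obs = ~mcar_mask
        for copy in cset.imputations:
            np.testing.assert_array_equal(copy[obs], severe_data.score[obs])

    @pytest.mark.parametrize("method", ["regress", "regress_round",
                                        "truncreg", "pmm"])
    def test_no_missingness_returns_input_for_all_copies(self, severe_data,
                                                         method):
        mask = np.zeros(severe_data.n, dtype=bool)
        cset = multiple_impute(severe_data, mask, method, m=2, rng=1)
        for copy in cset.imputations:
            np.testing.assert_array_equal(copy, severe_data.score)

    def test_truncreg_and_pmm_have_zero_out_of_range(self, severe_data,
                                                     mcar_mask):
        for method in ("truncreg", "pmm"):
            cset = multiple_impute(severe_data, mcar_mask, method, m=3, rng=2)
            assert cset.n_below.sum() == 0 and cset.n_above.sum() == 0
            assert cset.imputations.min() >= severe_data.lo
            assert cset.imputations.max() <= severe_data.hi

    def test_rounding_keeps_the_regress_counts_but_clamps_values(
            self, severe_data, mcar_mask):
        plain = multiple_impute(severe_data, mcar_mask, "regress", m=4, rng=3)
        clamp = multiple_impute(severe_data, mcar_mask, "regress_round",
                                m=4, rng=3)
        np.testing.assert_array_equal(plain.n_below, clamp.n_below)
        np.testing.assert_array_equal(plain.n_above, clamp.n_above)
        assert plain.n_below.sum() > 0
        assert clamp.imputations.min() >= severe_data.lo
        np.testing.assert_array_equal(
            clamp.imputations,
            np.clip(plain.imputations, severe_data.lo, severe_data.hi))

    def test_out_of_range_counts_match_bruteforce_recount(self, severe_data,
                                                          mcar_mask):
        cset = multiple_impute(severe_data, mcar_mask, "regress", m=4, rng=4)
        for i in range(cset.m):
            filled = cset.imputations[i, mcar_mask]
            assert cset.n_below[i] == np.sum(filled < severe_data.lo)
            assert cset.n_above[i] == np.sum(filled > severe_data.hi)

    def test_transformed_scale_round_trips_observed_values(self, severe_data,
                                                           mcar_mask):
        cset = multiple_impute(severe_data, mcar_mask, "pmm",
                               scale="transformed", m=2, rng=5)
        obs = ~mcar_mask
        np.testing.assert_array_equal(cset.imputations[0, obs],
                                      severe_data.score[obs])

    def test_rejects_bad_arguments(self, severe_data, mcar_mask):
        with pytest.raises(ValueError, match="method"):
            multiple_impute(severe_data, mcar_mask, "hotdeck")
        with pytest.raises(ValueError, match="scale"):
            multiple_impute(severe_data, mcar_mask, "pmm", scale="sqrt")
        with pytest.raises(ValueError, match="m >= 2"):
            multiple_impute(severe_data, mcar_mask, "pmm", m=1)
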