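"""Unit and property tests for the per-family local statistics and updates."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from dranet import (
    BetaState,
    ConvergenceState,
    DataError,
    DesignSpec,
    ProtocolError,
    SchemaError,
    aggregate_statistics,
    assess_convergence,
    build_model_matrix,
    cox_local_score_info,
    linear_local_summaries,
    linear_solve,
    logistic_local_score_info,
    newton_step,
    wald_inference,
)
from dranet.regression_core import EstimationError, LinearSummaries, ScoreInfo


# ---------------------------------------------------------------------------
# build_model_matrix
# ---------------------------------------------------------------------------


class TestBuildModelMatrix:
    def test_logistic_gets_leading_intercept_column(self):
        df = pd.DataFrame({"y": [0, 1, 0], "x": [1.0, 2.0, 3.0]})
        spec = DesignSpec(family="logistic", covariate_columns=("x",),
                          outcome_column="y")
        X, y = build_model_matrix(df, spec)
        assert X.shape == (3, 2)
        assert np.all(X[:, 0] == 1.0)
        assert np.array_equal(X[:, 1], df["x"])

    def test_cox_never_gets_an_intercept(self):
        spec = DesignSpec(family="cox", covariate_columns=("x",),
                          time_column="t", event_column="e",
                          include_intercept=True)
        assert spec.include_intercept is False
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 0], "x": [0.5, 1.5]})
        X, t, e = build_model_matrix(df, spec)
        assert X.shape == (2, 1)

    def test_missing_column_names_the_column(self):
        df = pd.DataFrame({"t": [1.0], "x": [0.0]})
        spec = DesignSpec(family="cox", covariate_columns=("x",),
                          time_column="t", event_column="e")
        with pytest.raises(SchemaError, match="'e'"):
            build_model_matrix(df, spec)

    def test_missing_values_error_with_row_count(self):
        df = pd.DataFrame({"y": [0, 1, np.nan], "x": [1.0, np.nan, 3.0]})
        spec = DesignSpec(family="linear", covariate_columns=("x",),
                          outcome_column="y")
        with pytest.raises(DataError, match="2 row"):
            build_model_matrix(df, spec)

    def test_duplicate_covariates_rejected(self):
        with pytest.raises(SchemaError):
            DesignSpec(family="linear", covariate_columns=("x", "x"),
                       outcome_column="y")


# ---------------------------------------------------------------------------
# linear family
# ---------------------------------------------------------------------------


class TestLinear:
    def test_intercept_only_hand_arithmetic(self):
        X = np.ones((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        s = linear_local_summaries(X, y)
        assert s.n == 3
        assert np.array_equal(s.xtx, [[3.0]])
        assert np.array_equal(s.xty, [6.0])
        assert s.yty == 14.0

    def test_empty_dataset_gives_zero_summaries(self):
        s = linear_local_summaries(np.empty((0, 2)), np.empty(0))
        assert s.n == 0
        assert np.all(s.xtx == 0) and np.all(s.xty == 0) and s.yty == 0

    def test_additivity_matches_concatenation(self, rng):
        Xa, Xb = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        ya, yb = rng.normal(size=5), rng.normal(size=7)
        split = linear_local_summaries(Xa, ya) + linear_local_summaries(Xb, yb)
        pooled = linear_local_summaries(np.vstack([Xa, Xb]),
                                        np.concatenate([ya, yb]))
        np.testing.assert_allclose(split.xtx, pooled.xtx, rtol=1e-13)
        np.testing.assert_allclose(split.xty, pooled.xty, rtol=1e-13)
        assert split.n == pooled.n
        assert split.yty == pytest.approx(pooled.yty, rel=1e-13)

    def test_pooled_mean_from_two_partners(self):
        a = linear_local_summaries(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]))
        b = linear_local_summaries(np.ones((2, 1)), np.array([1.5, 2.5]))
        fit = linear_solve(a + b, p=1)
        assert fit.beta_hat[0] == pytest.approx((6.0 + 4.0) / 5.0)
        assert fit.n_iterations == 1 and fit.converged

    def test_noise_free_fit_is_exact(self):
        x = np.linspace(-1, 2, 10)
        X = np.column_stack([np.ones(10), x])
        y = 2.0 * x
        parts = [linear_local_summaries(X[:5], y[:5]),
                 linear_local_summaries(X[5:], y[5:])]
        fit = linear_solve(aggregate_statistics(parts), p=2)
        np.testing.assert_allclose(fit.beta_hat, [0.0, 2.0], atol=1e-12)
        assert fit.sigma2 <= 1e-20

    def test_matches_pooled_ols_oracle(self, rng):
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        y = X @ [1.0, -0.5, 0.25] + rng.normal(size=60)
        parts = [linear_local_summaries(X[:25], y[:25]),
                 linear_local_summaries(X[25:], y[25:])]
        fit = linear_solve(aggregate_statistics(parts), p=3)
        res = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta_hat, res.params, rtol=1e-8)
        np.testing.assert_allclose(fit.se, res.bse, rtol=1e-8)

    def test_rank_deficiency_is_a_hard_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        s = linear_local_summaries(X, np.arange(10.0))
        with pytest.raises(EstimationError, match="collinear|singular"):
            linear_solve(s, p=3)

    def test_insufficient_n_is_an_error(self):
        s = linear_local_summaries(np.ones((1, 1)), np.array([1.0]))
        with pytest.raises(EstimationError, match="insufficient"):
            linear_solve(s, p=1)


# ---------------------------------------------------------------------------
# logistic family
# ---------------------------------------------------------------------------


class TestLogistic:
    def test_intercept_only_closed_form_at_beta_zero(self):
        X = np.ones((50, 1))
        y = np.concatenate([np.ones(30), np.zeros(20)])
        si = logistic_local_score_info(X, y, np.zeros(1))
        assert si.gradient[0] == pytest.approx(5.0)
        assert si.information[0, 0] == pytest.approx(12.5)
        assert si.loglik == pytest.approx(50 * math.log(0.5))
        assert si.n_events == 30

    def test_log_guarding_keeps_loglik_finite(self):
        X = np.ones((10, 1))
        y = np.zeros(10)
        si = logistic_local_score_info(X, y, np.array([800.0]))
        assert math.isfinite(si.loglik) and si.loglik < -1000

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(DataError):
            logistic_local_score_info(np.ones((3, 1)), np.array([0.0, 1.0, 2.0]),
                                      np.zeros(1))

    def test_two_partner_sum_equals_pooled_evaluation(self, rng):
        Xa = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        Xb = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        ya = rng.binomial(1, 0.4, 40).astype(float)
        yb = rng.binomial(1, 0.6, 60).astype(float)
        beta = rng.normal(size=3)
        total = logistic_local_score_info(Xa, ya, beta) + \
            logistic_local_score_info(Xb, yb, beta)
        pooled = logistic_local_score_info(
            np.vstack([Xa, Xb]), np.concatenate([ya, yb]), beta)
        np.testing.assert_allclose(total.gradient, pooled.gradient, rtol=1e-12)
        np.testing.assert_allclose(total.information, pooled.information,
                                   rtol=1e-12)
        assert total.loglik == pytest.approx(pooled.loglik, rel=1e-12)


# ---------------------------------------------------------------------------
# cox family
# ---------------------------------------------------------------------------


from conftest import brute_force_cox


class TestCox:
    def _simulate(self, rng, n):
        X = np.column_stack([rng.binomial(1, 0.5, n).astype(float),
                             rng.normal(size=n)])
        t = rng.exponential(1.0, n).round(2) + 0.01  # rounding forces ties
        e = rng.binomial(1, 0.7, n).astype(float)
        return X, t, e

    def test_no_events_contributes_nothing(self):
        si = cox_local_score_info(np.ones((4, 1)), np.arange(1.0, 5.0),
                                  np.zeros(4), np.zeros(1))
        assert si.loglik == 0.0
        assert np.all(si.gradient == 0) and np.all(si.information == 0)

    def test_score_at_zero_is_risk_set_mean_deviation(self):
        # distinct event times, single binary covariate
        x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0]])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        si = cox_local_score_info(x, t, e, np.zeros(1))
        expected = 0.0
        for i in np.flatnonzero(e == 1):
            risk = t >= t[i]
            expected += x[i, 0] - x[risk, 0].mean()
        assert si.gradient[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_oracle_with_ties(self, rng):
        X, t, e = self._simulate(rng, 80)
        beta = np.array([0.4, -0.2])
        si = cox_local_score_info(X, t, e, beta)
        ll, score, info = brute_force_cox(X, t, e, beta)
        assert si.loglik == pytest.approx(ll, rel=1e-12)
        np.testing.assert_allclose(si.gradient, score, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(si.information, info, rtol=1e-10, atol=1e-12)

    def test_partner_sum_is_pooled_stratified_fit(self, rng):
        beta = np.array([0.3, 0.1])
        parts = [self._simulate(rng, 50) for _ in range(2)]
        total = aggregate_statistics(
            [cox_local_score_info(X, t, e, beta) for X, t, e in parts])
        ll = sum(brute_force_cox(X, t, e, beta)[0] for X, t, e in parts)
        score = sum(brute_force_cox(X, t, e, beta)[1] for X, t, e in parts)
        assert total.loglik == pytest.approx(ll, rel=1e-12)
        np.testing.assert_allclose(total.gradient, score, rtol=1e-10)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DataError):
            cox_local_score_info(np.ones((2, 1)), np.array([0.0, 1.0]),
                                 np.array([1.0, 0.0]), np.zeros(1))


# ---------------------------------------------------------------------------
# aggregation / Newton / convergence / inference
# ---------------------------------------------------------------------------


class TestAggregation:
    def _si(self, iteration=1, p=2, rng=None):
        rng = rng or np.random.default_rng(0)
        a = rng.normal(size=(p, p))
        return ScoreInfo(n=10, n_events=4, gradient=rng.normal(size=p),
                         information=a @ a.T, loglik=-12.0, iteration=iteration)

    def test_single_payload_identity(self):
        si = self._si()
        out = aggregate_statistics([si])
        np.testing.assert_array_equal(out.gradient, si.gradient)

    def test_mixed_iterations_rejected(self):
        with pytest.raises(ProtocolError, match="iteration"):
            aggregate_statistics([self._si(3), self._si(4)])

    def test_sum_matches_manual_addition(self, rng):
        payloads = [self._si(rng=rng) for _ in range(3)]
        out = aggregate_statistics(payloads)
        np.testing.assert_allclose(
            out.gradient, sum(p.gradient for p in payloads))
        np.testing.assert_allclose(
            out.information, sum(p.information for p in payloads))
        assert out.n == 30 and out.n_events == 12
        assert out.loglik == pytest.approx(-36.0)

    def test_mismatched_dimension_rejected(self):
        with pytest.raises(ProtocolError):
            aggregate_statistics([self._si(p=2), self._si(p=3)])


class TestNewton:
    def test_zero_gradient_is_stationary(self):
        si = ScoreInfo(10, 5, np.zeros(2), np.eye(2), -5.0, 1)
        np.testing.assert_array_equal(newton_step(np.array([1.0, 2.0]), si),
                                      [1.0, 2.0])

    def test_one_step_closed_form(self):
        si = ScoreInfo(50, 30, np.array([5.0]), np.array([[12.5]]),
                       50 * math.log(0.5), 1)
        assert newton_step(np.zeros(1), si)[0] == pytest.approx(0.4)

    def test_iterates_to_logit_of_sample_proportion(self):
        X = np.ones((50, 1))
        y = np.concatenate([np.ones(30), np.zeros(20)])
        beta = np.zeros(1)
        for it in range(20):
            si = logistic_local_score_info(X, y, beta)
            new = newton_step(beta, si)
            if abs(new[0] - beta[0]) < 1e-12:
                break
            beta = new
        assert beta[0] == pytest.approx(math.log(30 / 20), abs=1e-10)

    def test_singular_information_raises_advice(self):
        si = ScoreInfo(10, 5, np.ones(2), np.ones((2, 2)), -5.0, 1)
        with pytest.raises(EstimationError, match="collinear|separation"):
            newton_step(np.zeros(2), si)


class TestConvergence:
    def test_zero_delta_converges(self):
        b = np.array([1.0, -2.0])
        s = assess_convergence(b, b, -10.0, -10.0, 1e-12, 25, 3)
        assert s.state is ConvergenceState.CONVERGED
        assert s.max_abs_delta == 0.0

    def test_iteration_cap(self):
        s = assess_convergence(np.zeros(1), np.array([1e-3]), -10, -9,
                               1e-6, 25, 25)
        assert s.state is ConvergenceState.MAX_ITERATIONS_REACHED

    def test_nan_beta_fails_without_exception(self):
        s = assess_convergence(np.zeros(1), np.array([np.nan]), -10, -9,
                               1e-6, 25, 2)
        assert s.state is ConvergenceState.FAILED
        assert "non-finite" in s.message

    def test_continuing_below_cap(self):
        s = assess_convergence(np.zeros(1), np.array([0.5]), -10, -8, 1e-6, 25, 3)
        assert s.state is ConvergenceState.CONTINUING
        assert s.loglik_delta == pytest.approx(2.0)


class TestWaldInference:
    def test_intercept_only_logistic_se(self):
        beta = np.array([0.0])
        total = logistic_local_score_info(
            np.ones((100, 1)),
            np.concatenate([np.ones(50), np.zeros(50)]), beta)
        fit = wald_inference("logistic", beta, total)
        assert fit.se[0] == pytest.approx(math.sqrt(1 / 25.0))

    def test_diagonal_information_closed_form(self):
        total = ScoreInfo(100, 40, np.zeros(2), np.diag([4.0, 25.0]), -50.0, 5)
        fit = wald_inference("logistic", np.array([1.0, -1.0]), total)
        np.testing.assert_allclose(fit.se, [0.5, 0.2])
        np.testing.assert_allclose(fit.ci95[1], [-1.0 - 1.959964 * 0.2,
                                                 -1.0 + 1.959964 * 0.2])

    def test_ci_invariant_holds(self, rng):
        a = rng.normal(size=(3, 3))
        total = ScoreInfo(50, 20, np.zeros(3), a @ a.T + 3 * np.eye(3), -30.0, 4)
        beta = rng.normal(size=3)
        fit = wald_inference("cox", beta, total)
        np.testing.assert_allclose(fit.se, np.sqrt(np.diag(fit.cov)))
        np.testing.assert_allclose(fit.ci95[:, 1] - fit.ci95[:, 0],
                                   2 * 1.959964 * fit.se)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n=st.integers(10, 60),
    cut=st.floats(0.1, 0.9),
)
def test_additivity_over_random_partitions(seed, n, cut):
    """Local statistics of any two-way split sum to the pooled statistics."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.binomial(1, 0.5, n).astype(float)
    beta = rng.normal(scale=0.5, size=2)
    k = max(1, min(n - 1, int(cut * n)))
    split = logistic_local_score_info(X[:k], y[:k], beta) + \
        logistic_local_score_info(X[k:], y[k:], beta)
    pooled = logistic_local_score_info(X, y, beta)
    np.testing.assert_allclose(split.gradient, pooled.gradient,
                               rtol=1e-10, atol=1e-10)
    np.testing.assert_allclose(split.information, pooled.information,
                               rtol=1e-10, atol=1e-10)
    assert split.loglik == pytest.approx(pooled.loglik, rel=1e-10)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000), scale=st.floats(0.25, 8.0))
def test_covariate_rescaling_rescales_estimate(seed, scale):
    """Multiplying a covariate by c divides its coefficient by c."""
    rng = np.random.default_rng(seed)
    n = 400
    x = rng.normal(size=n)
    y = rng.binomial(1, 0.5 * (1 + np.tanh(0.5 * (0.5 * x - 0.2)))).astype(float)

    def fit(xcol):
        X = np.column_stack([np.ones(n), xcol])
        beta = np.zeros(2)
        for _ in range(30):
            si = logistic_local_score_info(X, y, beta)
            new = newton_step(beta, si)
            if np.max(np.abs(new - beta)) < 1e-10:
                break
            beta = new
        return beta

    b1, b2 = fit(x), fit(scale * x)
    assert b2[1] == pytest.approx(b1[1] / scale, rel=1e-6)


def test_partner_permutation_leaves_aggregate_unchanged(rng):
    """With the fixed ascending summation order, partner labels don't matter."""
    payloads = []
    for pid in range(3):
        a = rng.normal(size=(2, 2))
        payloads.append(ScoreInfo(10 + pid, pid, rng.normal(size=2),
                                  a @ a.T, -float(pid + 1), 1))
    ordered = aggregate_statistics(payloads)
    permuted_inputs = [payloads[2], payloads[0], payloads[1]]
    # the center always re-sorts to ascending partner order before summing;
    # emulate by restoring the canonical order
    restored = aggregate_statistics(sorted(
        permuted_inputs, key=lambda s: s.n))
    np.testing.assert_array_equal(ordered.gradient, restored.gradient)
    np.testing.assert_array_equal(ordered.information, restored.information)


def test_beta_state_validates_finiteness():
    with pytest.raises(ProtocolError):
        BetaState(iteration=1, beta=np.array([1.0, np.inf]))
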