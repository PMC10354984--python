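import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import bh_oracle
from methpanel.stats import (
    RankDeficientDesignError,
    bh_adjust,
    fisher_combine,
    fit_linear_model,
    fit_linear_models,
    moderate_variances,
    moderated_t_test,
    trigamma_inverse,
    ModerationResult,
)


class TestFitLinearModel:
    def test_response_equals_design_column(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        fit = fit_linear_model(X[:, 1], X)
        assert fit.coefficients[1] == pytest.approx(1.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_intercept_only_gives_mean(self):
        y = np.array([3.0, 5.0, 7.0, 9.0])
        fit = fit_linear_model(y, np.ones((4, 1)))
        assert fit.coefficients[0] == pytest.approx(y.mean())
        assert fit.residual_df == 3

    def test_matches_hand_computed_normal_equations(self):
        # X'X = [[6,15],[15,55]], X'y = [19,64] -> beta = (0.80952381, 0.94285714)
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.array([1, 2, 2, 4, 4, 6], float)
        fit = fit_linear_model(y, X)
        assert fit.coefficients == pytest.approx([0.80952381, 0.94285714])

    def test_rank_deficient_raises_naming_columns(self):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(RankDeficientDesignError) as e:
            fit_linear_model(np.zeros(8), X, column_names=["a", "b", "c"])
        assert set(e.value.columns) & {"b", "c"}

    def test_n_le_rank_raises(self):
        with pytest.raises(ValueError):
            fit_linear_model(np.zeros(2), np.eye(2))

    def test_vectorised_agrees_with_single(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        Y = rng.normal(size=(20, 5))
        coefs, su, s2, df = fit_linear_models(Y, X)
        for j in range(5):
            fit = fit_linear_model(Y[:, j], X)
            assert coefs[:, j] == pytest.approx(fit.coefficients)
            assert s2[j] == pytest.approx(fit.residual_variance)
            assert su == pytest.approx(fit.stdev_unscaled)
            assert df == fit.residual_df


class TestModerateVariances:
    def test_no_shrinkage_limit(self):
        s2 = np.array([1.0, 2.0, 3.0])
        from methpanel.stats import _posterior_variances

        assert _posterior_variances(s2, 10.0, 0.0, 5.0) == pytest.approx(s2)

    def test_complete_pooling_limit(self):
        s2 = np.array([1.0, 2.0, 3.0])
        from methpanel.stats import _posterior_variances

        post = _posterior_variances(s2, 10.0, np.inf, 1.7)
        assert post == pytest.approx([1.7, 1.7, 1.7])

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(8, 500) / 8
        res = moderate_variances(s2, 8)
        lo = np.minimum(res.prior_variance, s2)
        hi = np.maximum(res.prior_variance, s2)
        assert np.all(res.posterior_variances >= lo - 1e-12)
        assert np.all(res.posterior_variances <= hi + 1e-12)

    def test_invariant_formula(self):
        # heterogeneous true variances keep the estimated prior df finite
        rng = np.random.default_rng(3)
        sigma2 = np.exp(rng.normal(0, 1, 200))
        s2 = sigma2 * rng.chisquare(6, 200) / 6
        res = moderate_variances(s2, 6)
        d0, s0 = res.prior_df, res.prior_variance
        assert np.isfinite(d0)
        expect = (d0 * s0 + 6 * s2) / (d0 + 6)
        assert res.posterior_variances == pytest.approx(expect)

    def test_parameter_recovery_scaled_inv_chisq(self):
        # variances ~ s0^2 * d0 / chi2_{d0} scaled-inverse-chi-square mixture:
        # sample s2_g | sigma_g^2 ~ sigma_g^2 chi2_d / d with known d0=4, s0=1
        d0, s0_2, d = 4.0, 1.0, 16
        rng = np.random.default_rng(4)
        reps_d0, reps_s0 = [], []
        for _ in range(5):
            sigma2 = d0 * s0_2 / rng.chisquare(d0, 1000)
            s2 = sigma2 * rng.chisquare(d, 1000) / d
            res = moderate_variances(s2, d)
            reps_d0.append(res.prior_df)
            reps_s0.append(res.prior_variance)
        assert abs(np.median(reps_d0) - d0) / d0 < 0.2
        assert abs(np.median(reps_s0) - s0_2) / s0_2 < 0.2

    def test_fallback_on_single_variance(self):
        with pytest.warns(RuntimeWarning):
            res = moderate_variances(np.array([1.0, 0.0]), 5)
        assert res.no_shrinkage_fallback
        assert res.prior_df == 0.0

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in [0.1, 1.0, 5.0, 50.0]:
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def _fit(self, seed=5, n=12):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        return fit_linear_model(y, X)

    def test_zero_coefficient(self):
        fit = self._fit()
        fit.coefficients[1] = 0.0
        mod = ModerationResult(prior_df=4.0, prior_variance=1.0,
                               posterior_variances=np.array([1.0]),
                               total_df=np.array([fit.residual_df + 4.0]))
        t, p, _ = moderated_t_test(fit, mod, 1)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_d0_zero_equals_ordinary_t(self):
        fit = self._fit()
        mod = ModerationResult(prior_df=0.0, prior_variance=1.0,
                               posterior_variances=np.array([fit.residual_variance]),
                               total_df=np.array([float(fit.residual_df)]))
        t, p, _ = moderated_t_test(fit, mod, 1)
        se = fit.stdev_unscaled[1] * np.sqrt(fit.residual_variance)
        t_ref = fit.coefficients[1] / se
        p_ref = 2 * sps.t.sf(abs(t_ref), fit.residual_df)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_d0_infinite_is_normal_test(self):
        fit = self._fit()
        s0 = 1.3
        mod = ModerationResult(prior_df=np.inf, prior_variance=s0,
                               posterior_variances=np.array([s0]),
                               total_df=np.array([np.inf]))
        t, p, ci = moderated_t_test(fit, mod, 1)
        se = fit.stdev_unscaled[1] * np.sqrt(s0)
        assert t == pytest.approx(fit.coefficients[1] / se)
        assert p == pytest.approx(2 * sps.norm.sf(abs(t)))
        assert ci[1] - ci[0] == pytest.approx(2 * 1.959963985 * se, rel=1e-6)


class TestBHAdjust:
    def test_single_value(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_worked_example(self):
        q = bh_adjust([0.004, 0.03, 0.04, 0.8])
        assert q == pytest.approx([0.016, 0.05333333, 0.05333333, 0.8])

    def test_against_oracle_all_permutations(self):
        from itertools import permutations

        base = [0.001, 0.02, 0.04, 0.2, 0.6, 1.0]
        for perm in permutations(base):
            assert bh_adjust(list(perm)) == pytest.approx(bh_oracle(list(perm)))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_property_q_ge_p_and_oracle(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        assert q == pytest.approx(bh_oracle(p))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisherCombine:
    def test_k1_identity(self):
        assert fisher_combine([0.3]) == pytest.approx(0.3)

    def test_k2_closed_form(self):
        # X2 = -2 ln(0.25) = 2.7726; chi2_4 survival (1 + x/2) e^{-x/2}
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5965735903, rel=1e-9)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_zero_warns(self):
        with pytest.warns(RuntimeWarning):
            assert fisher_combine([0.0, 0.5]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    def test_uniform_under_null(self):
        rng = np.random.default_rng(7)
        draws = rng.uniform(size=(10_000, 10))
        combined = np.array([fisher_combine(row) for row in draws])
        stat, p = sps.kstest(combined, "uniform")
        assert p > 0.01
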