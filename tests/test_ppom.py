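import numpy as np
import pytest
from scipy import special

from eqmap.design import CovariateDesign, RankDeficientError
from eqmap.ppom import (
    AbsentLevelError,
    PPOMError,
    PPOMFit,
    PPOMSpec,
    autofit,
    fit_ppom,
    negative_log_likelihood,
    parallel_lines_wald,
    predict_probs,
)

from conftest import simulate_ordinal


def _empty_design(n: int) -> CovariateDesign:
    return CovariateDesign((), np.empty((n, 0)))


class TestLikelihood:
    def test_intercept_only_saturated_value(self):
        # cut points at the empirical cumulative logits reproduce the
        # multinomial saturated likelihood n * sum f * (-log f)
        d = np.array([1] * 18 + [2] * 9 + [3] * 3)
        n = d.size
        freqs = np.array([18, 9, 3]) / n
        cum = np.cumsum(freqs)
        params = np.array([special.logit(cum[0]), special.logit(cum[1])])
        nll = negative_log_likelihood(params, _empty_design(n), d, PPOMSpec((), ()))
        expected = n * np.sum(freqs * -np.log(freqs))
        assert nll == pytest.approx(expected, abs=1e-10)

    def test_intercept_only_mle_by_grid_search(self):
        # brute-force the two cut points on a 30-row fixture and check
        # the closed-form cumulative logits are the arg-minimum
        d = np.array([1] * 18 + [2] * 9 + [3] * 3)
        design = _empty_design(d.size)
        spec = PPOMSpec((), ())
        grid = np.linspace(-3, 3, 121)
        best, best_params = np.inf, None
        for k1 in grid:
            for k2 in grid:
                if k2 <= k1:
                    continue
                val = negative_log_likelihood(np.array([k1, k2]), design, d, spec)
                if val < best:
                    best, best_params = val, (k1, k2)
        closed = (special.logit(0.6), special.logit(0.9))
        assert best_params == pytest.approx(closed, abs=0.05)
        fit = fit_ppom(design, d)
        assert (fit.k1, fit.k2) == pytest.approx(closed, abs=1e-6)

    def test_single_row_likelihood(self):
        # one row with d=1 and parameters putting p1 = 0.5
        d = np.array([1])
        params = np.array([0.0, 2.0])  # k1 = 0 -> p1 = logistic(0) = 0.5
        nll = negative_log_likelihood(params, _empty_design(1), d, PPOMSpec((), ()))
        assert nll == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_matches_ordered_logit_oracle_at_same_params(self, parallel_fixture):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        design, d = parallel_fixture
        beta = np.array([0.7, -0.4])
        k1, k2 = -0.2, 1.3
        spec = PPOMSpec.all_parallel(design.columns)
        ours = negative_log_likelihood(np.array([*beta, k1, k2]), design, d, spec)
        model = OrderedModel(d - 1, design.matrix, distr="logit")
        # statsmodels packs the second threshold as a log-increment
        sm_params = np.array([*beta, k1, np.log(k2 - k1)])
        theirs = -model.loglike(sm_params)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_wrong_param_length_rejected(self, parallel_fixture):
        design, d = parallel_fixture
        with pytest.raises(PPOMError, match="packed parameters"):
            negative_log_likelihood(
                np.zeros(3), design, d, PPOMSpec.all_parallel(design.columns)
            )


class TestFitting:
    def test_all_parallel_matches_proportional_odds_oracle(self, parallel_fixture):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        design, d = parallel_fixture
        fit = fit_ppom(design, d, gtol=1e-10)
        model = OrderedModel(d - 1, design.matrix, distr="logit")
        res = model.fit(method="bfgs", gtol=1e-11, maxiter=5000, disp=0)
        thresholds = model.transform_threshold_params(res.params)
        np.testing.assert_allclose(fit.beta_eq1, res.params[:2], atol=1e-6)
        assert fit.k1 == pytest.approx(thresholds[1], abs=1e-6)
        assert fit.k2 == pytest.approx(thresholds[2], abs=1e-6)
        assert fit.log_likelihood == pytest.approx(res.llf, abs=1e-6)
        # standard errors from the observed information agree too
        np.testing.assert_allclose(fit.se[:2], res.bse[:2], rtol=1e-3)

    def test_relaxing_a_constraint_never_lowers_loglik(self, parallel_fixture):
        design, d = parallel_fixture
        ll_prev = fit_ppom(design, d).log_likelihood
        for spec in (
            PPOMSpec.with_free(design.columns, ["x1"]),
            PPOMSpec.unconstrained(design.columns),
        ):
            ll = fit_ppom(design, d, spec).log_likelihood
            assert ll >= ll_prev - 1e-8
            ll_prev = ll

    def test_parallel_covariates_share_one_parameter(self, parallel_fixture):
        design, d = parallel_fixture
        fit = fit_ppom(design, d, PPOMSpec.with_free(design.columns, ["x2"]))
        assert fit.beta_eq1[0] == fit.beta_eq2[0]  # same packed parameter
        assert fit.beta_eq1[1] != fit.beta_eq2[1]

    def test_covariance_is_symmetric_psd(self, parallel_fixture):
        design, d = parallel_fixture
        fit = fit_ppom(design, d, PPOMSpec.unconstrained(design.columns))
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(fit.cov).min() > -1e-10

    def test_shift_invariance(self, parallel_fixture):
        # adding a constant to a covariate only shifts the cut points
        design, d = parallel_fixture
        fit = fit_ppom(design, d, gtol=1e-9)
        shifted = CovariateDesign(
            design.columns, design.matrix + np.array([2.0, 0.0])
        )
        fit2 = fit_ppom(shifted, d, gtol=1e-9)
        p1 = predict_probs(fit, design).probs
        p2 = predict_probs(fit2, shifted).probs
        np.testing.assert_allclose(p1, p2, atol=1e-8)
        assert fit2.k1 == pytest.approx(fit.k1 + 2.0 * fit.beta_eq1[0], abs=1e-6)

    def test_absent_level_raises_with_advice(self):
        d = np.array([1, 2, 1, 2, 1])
        with pytest.raises(AbsentLevelError, match="collapse_absent"):
            fit_ppom(_empty_design(5), d)

    def test_collapse_fits_binary_logit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        prob_problem = special.expit(0.8 * x - 0.5)
        d = 1 + (rng.random(500) < prob_problem).astype(int)  # levels 1/2 only
        design = CovariateDesign(("x",), x[:, None])
        fit = fit_ppom(design, d, collapse_absent=True)
        assert fit.collapsed and not fit.degenerate
        probs = predict_probs(fit, design).probs
        np.testing.assert_array_equal(probs[:, 2], 0.0)
        # recovers the binary-logit truth roughly
        assert fit.beta_eq1[0] == pytest.approx(0.8, abs=0.3)

    def test_degenerate_constant_response_is_smoothed(self):
        d = np.ones(200, dtype=int)
        fit = fit_ppom(_empty_design(200), d, collapse_absent=True)
        assert fit.degenerate
        probs = predict_probs(fit, _empty_design(3)).probs
        assert probs[0, 0] == pytest.approx(1.0, abs=0.01)

    def test_rank_deficient_design_is_named(self):
        x = np.arange(30, dtype=float)
        design = CovariateDesign(("a", "double_a"), np.column_stack([x, 2 * x]))
        d = np.tile([1, 2, 3], 10)
        with pytest.raises(RankDeficientError, match="double_a"):
            fit_ppom(design, d)

    def test_parameter_recovery_single_cohort(self):
        design, d = simulate_ordinal(
            20_000, beta_eq1=[0.5, 0.3], beta_eq2=[0.5, 0.9],
            k1=-0.2, k2=2.0, seed=11,
        )
        spec = PPOMSpec.with_free(design.columns, ["x2"])
        fit = fit_ppom(design, d, spec)
        truth = {"x1": 0.5, "x2:eq1": 0.3, "x2:eq2": 0.9, "k1": -0.2, "k2": 2.0}
        for name, true_val in truth.items():
            i = fit.param_names.index(name)
            assert abs(fit.theta[i] - true_val) < 3 * fit.se[i]


class TestPrediction:
    def test_intercept_only_predicts_sample_frequencies(self):
        d = np.array([1] * 60 + [2] * 30 + [3] * 10)
        fit = fit_ppom(_empty_design(100), d)
        probs = predict_probs(fit, _empty_design(4)).probs
        np.testing.assert_allclose(probs, np.tile([0.6, 0.3, 0.1], (4, 1)), atol=1e-6)

    def test_rows_sum_to_one(self, parallel_fixture):
        design, d = parallel_fixture
        fit = fit_ppom(design, d, PPOMSpec.unconstrained(design.columns))
        probs = predict_probs(fit, design).probs
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_crossing_predictors_flag_negative_p2(self):
        # beta_eq2 >> beta_eq1 makes P(d<=2) < P(d<=1) at large x
        fit = PPOMFit.from_params(
            ("x",), (False,), beta_eq1=[0.0], beta_eq2=[2.0], k1=0.0, k2=1.0
        )
        design = CovariateDesign(("x",), np.array([[0.0], [3.0]]))
        pred = predict_probs(fit, design)
        assert not pred.negative_p2[0]
        assert pred.negative_p2[1]
        np.testing.assert_allclose(pred.probs.sum(axis=1), 1.0, atol=1e-12)
        assert pred.probs[1, 1] == 0.0

    def test_column_mismatch_is_listed(self, parallel_fixture):
        design, d = parallel_fixture
        fit = fit_ppom(design, d)
        other = CovariateDesign(("x1", "zzz"), design.matrix)
        with pytest.raises(PPOMError, match="zzz"):
            predict_probs(fit, other)


class TestWaldAndAutofit:
    def test_requires_unconstrained_fit(self, parallel_fixture):
        design, d = parallel_fixture
        fit = fit_ppom(design, d)
        with pytest.raises(PPOMError, match="unconstrained"):
            parallel_lines_wald(fit)

    def test_equal_estimates_give_zero_statistic(self):
        fit = PPOMFit.from_params(
            ("x",), (False,), beta_eq1=[0.4], beta_eq2=[0.4], k1=0.0, k2=1.0
        )
        fit.cov = np.eye(4)
        table = parallel_lines_wald(fit)
        assert table.loc["x", "statistic"] == 0.0
        assert table.loc["x", "pvalue"] == 1.0

    def test_singular_subblock_reports_undefined(self):
        fit = PPOMFit.from_params(
            ("x",), (False,), beta_eq1=[0.4], beta_eq2=[0.6], k1=0.0, k2=1.0
        )
        table = parallel_lines_wald(fit)  # cov is all zeros
        assert np.isnan(table.loc["x", "statistic"])

    def test_power_against_large_violation(self):
        design, d = simulate_ordinal(
            20_000, beta_eq1=[0.3, 0.2], beta_eq2=[0.3, 1.2], k1=-0.2, k2=2.2, seed=5
        )
        fit = fit_ppom(design, d, PPOMSpec.unconstrained(design.columns))
        table = parallel_lines_wald(fit)
        assert table.loc["x2", "pvalue"] < 1e-3
        assert table.loc["x1", "pvalue"] > 1e-3

    def test_autofit_alpha_one_leaves_everything_free(self, parallel_fixture):
        design, d = parallel_fixture
        spec, _ = autofit(design, d, alpha=1.0)
        assert spec.n_free == len(design.columns)

    def test_autofit_tiny_alpha_constrains_everything(self, parallel_fixture):
        design, d = parallel_fixture
        spec, fit = autofit(design, d, alpha=1e-12)
        assert spec.n_free == 0
        parallel = fit_ppom(design, d)
        assert fit.log_likelihood == pytest.approx(parallel.log_likelihood, abs=1e-6)

    def test_autofit_recovers_parallel_truth(self):
        design, d = simulate_ordinal(
            20_000, beta_eq1=[0.6, 0.4, -0.3], beta_eq2=[0.6, 0.4, -0.3],
            k1=-0.3, k2=1.8, seed=21, n_continuous=2, n_binary=1,
        )
        spec, _ = autofit(design, d, alpha=0.05)
        # under parallel truth most covariates should end up constrained
        assert spec.n_free <= 1
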