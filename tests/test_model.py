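"""Quadratic model representation, fitting, ANOVA and simplification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import random_quadratic
from fermrsm.design import DesignTable, generate_ccd
from fermrsm.model import (
    QuadraticModel,
    drop_insignificant,
    fit,
    lack_of_fit_test,
    main_effect_ranking,
    model_matrix,
    partial_correlation,
    simplify,
)
from fermrsm.reference import TERM_PVALUES


class TestEvaluate:
    def test_intercept_at_origin(self, ref_model):
        assert ref_model.evaluate([0, 0, 0, 0]) == 9.72944

    def test_reported_optimum_rounds_to_40mm(self, ref_model):
        y = ref_model.evaluate([2.188, -1.518, -1.066, 0.0])
        assert round(y) == 40

    def test_zero_model_everywhere_zero(self):
        zero = QuadraticModel.from_coefficients(["a", "b"], {})
        assert zero.evaluate([3.7, -1.2]) == 0.0

    def test_dimension_mismatch_rejected(self, ref_model):
        with pytest.raises(ValueError, match="dimension"):
            ref_model.evaluate([1.0, 2.0])

    def test_batch_matches_single(self, ref_model):
        pts = np.array([[0.5, -0.5, 1.0, 2.0], [1, 1, 1, 1]])
        batch = ref_model.evaluate(pts)
        assert batch == pytest.approx([ref_model.evaluate(p) for p in pts])

    @settings(deadline=None)
    @given(seed=st.integers(0, 1000), scale=st.floats(-2, 2))
    def test_linear_in_coefficients(self, seed, scale):
        rng = np.random.default_rng(seed)
        m = random_quadratic(rng, 3)
        scaled = QuadraticModel.from_coefficients(
            m.factors, {k: scale * v for k, v in m.coefficients().items()}
        )
        x = rng.uniform(-2, 2, 3)
        assert scaled.evaluate(x) == pytest.approx(scale * m.evaluate(x), abs=1e-9)

    def test_coefficient_roundtrip(self, ref_model):
        again = QuadraticModel.from_coefficients(ref_model.factors, ref_model.coefficients())
        assert again.coefficients() == ref_model.coefficients()


class TestFit:
    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_zero_noise_recovery(self, k):
        rng = np.random.default_rng(k)
        truth = random_quadratic(rng, k)
        design = generate_ccd(truth.factors, n_center=5)
        table = design.with_response(truth.evaluate(design.coded))
        result = fit(table)
        for label, value in truth.coefficients().items():
            assert result.model.coefficients()[label] == pytest.approx(value, abs=1e-8)

    def test_saturated_model_interpolates(self):
        # 6 points, 6 terms in 2 factors: exact interpolation by direct solve
        pts = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1]], dtype=float)
        rng = np.random.default_rng(5)
        y = rng.normal(size=6)
        beta_direct = np.linalg.solve(model_matrix(pts), y)
        table = DesignTable(factors=["a", "b"], coded=pts, response=y)
        result = fit(table)
        assert result.rss == pytest.approx(0.0, abs=1e-18)
        assert result.fitted == pytest.approx(y)
        assert model_matrix(pts) @ beta_direct == pytest.approx(result.fitted)

    def test_estimates_unbiased_within_three_se(self):
        rng = np.random.default_rng(42)
        truth = random_quadratic(rng, 2)
        design = generate_ccd(truth.factors, n_center=5)  # 13-run CCD
        X = model_matrix(design.coded)
        sd = 0.7
        se = sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        mean_y = truth.evaluate(design.coded)
        n_sim = 200
        estimates = []
        for _ in range(n_sim):
            table = design.with_response(mean_y + rng.normal(0, sd, len(mean_y)))
            estimates.append(list(fit(table).model.coefficients().values()))
        mean_est = np.mean(estimates, axis=0)
        truth_vec = np.array(list(truth.coefficients().values()))
        assert np.all(np.abs(mean_est - truth_vec) < 3 * se / math.sqrt(n_sim))

    def test_rank_deficiency_names_collinear_columns(self):
        coded = np.array([[0, 0], [1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 6]], dtype=float)
        table = DesignTable(factors=["a", "b"], coded=coded, response=np.arange(7.0))
        with pytest.raises(np.linalg.LinAlgError, match="singular design"):
            fit(table)

    def test_missing_response_rejected(self):
        with pytest.raises(ValueError, match="no responses"):
            fit(generate_ccd(["a", "b"], n_center=3))


@pytest.fixture(scope="module")
def noisy_fit():
    rng = np.random.default_rng(3)
    truth = random_quadratic(rng, 3)
    design = generate_ccd(truth.factors, n_center=6)
    y = truth.evaluate(design.coded) + rng.normal(0, 1.0, design.n_runs)
    return fit(design.with_response(y))


class TestAnova:

    def test_additivity_identities(self, noisy_fit):
        a = noisy_fit.anova
        assert a.ss_regression + a.ss_residual == pytest.approx(a.ss_total, rel=1e-9)
        assert a.ss_lack_of_fit + a.ss_pure_error == pytest.approx(a.ss_residual, rel=1e-9)
        assert a.df_regression + a.df_residual == a.df_total
        assert a.df_lack_of_fit + a.df_pure_error == a.df_residual

    def test_pure_error_df_from_center_replicates(self, noisy_fit):
        # 6 identical center runs contribute 5 pure-error df
        assert noisy_fit.anova.df_pure_error == 5

    def test_seven_center_replicates_give_six_df(self):
        rng = np.random.default_rng(9)
        truth = random_quadratic(rng, 4)
        design = generate_ccd(truth.factors, n_center=7)
        y = truth.evaluate(design.coded) + rng.normal(0, 1.0, design.n_runs)
        assert fit(design.with_response(y)).anova.df_pure_error == 6

    def test_partial_ss_matches_projection_oracle(self, noisy_fit):
        # drop-one SS == y' (P_full - P_reduced) y with explicit projectors
        design, a = noisy_fit.design, noisy_fit.anova
        X = model_matrix(design.coded)
        y = design.response

        def proj(M):
            return M @ np.linalg.pinv(M)

        P_full = proj(X)
        for j, term in enumerate(a.terms.index, start=1):
            keep = [c for c in range(X.shape[1]) if c != j]
            expected = float(y @ (P_full - proj(X[:, keep])) @ y)
            assert a.terms.loc[term, "SS"] == pytest.approx(expected, rel=1e-8, abs=1e-10)

    def test_term_f_is_partial_ms_over_residual_ms(self, noisy_fit):
        a = noisy_fit.anova
        ms_res = a.ss_residual / a.df_residual
        for term in a.terms.index:
            assert a.terms.loc[term, "F"] == pytest.approx(
                a.terms.loc[term, "SS"] / ms_res
            )

    def test_no_replicates_flags_lack_of_fit_unavailable(self):
        rng = np.random.default_rng(1)
        truth = random_quadratic(rng, 2)
        design = generate_ccd(truth.factors, n_center=1)
        y = truth.evaluate(design.coded) + rng.normal(0, 1, design.n_runs)
        result = fit(design.with_response(y))
        assert not result.anova.has_pure_error
        with pytest.raises(ValueError, match="replicate"):
            lack_of_fit_test(result.anova)


class TestLackOfFit:
    def test_critical_value_matches_published_quantile(self):
        assert stats.f.ppf(0.95, 10, 6) == pytest.approx(4.06, abs=5e-3)

    def test_adequate_when_misfit_zero(self):
        rng = np.random.default_rng(2)
        truth = random_quadratic(rng, 2)
        design = generate_ccd(truth.factors, n_center=4)
        mean_y = truth.evaluate(design.coded)
        noise = np.zeros(design.n_runs)
        center = np.all(design.coded == 0, axis=1)
        noise[center] = rng.normal(0, 0.5, center.sum())  # pure error only
        result = fit(design.with_response(mean_y + noise))
        lof = lack_of_fit_test(result.anova)
        assert lof.adequate and lof.f_statistic < 1.0

    def test_missing_cubic_effect_detected_at_high_signal(self):
        # truth has a strong cubic term the quadratic model cannot absorb
        rng = np.random.default_rng(4)
        design = generate_ccd(["a", "b"], n_center=6)
        x = design.coded
        mean_y = 1.0 + 2 * x[:, 0] + 25.0 * x[:, 0] ** 3
        reps = []
        for rep in range(20):
            y = mean_y + rng.normal(0, 0.3, design.n_runs)
            lof = lack_of_fit_test(fit(design.with_response(y)).anova)
            reps.append(lof.adequate)
        assert sum(reps) <= 2  # nearly always declared inadequate

    def test_zero_pure_error_reports_caveat(self):
        rng = np.random.default_rng(8)
        design = generate_ccd(["a", "b"], n_center=4)
        mean_y = 5.0 + 10.0 * design.coded[:, 0] ** 3  # misfit, no replicate noise
        lof = lack_of_fit_test(fit(design.with_response(mean_y)).anova)
        assert not lof.adequate and math.isinf(lof.f_statistic) and lof.caveat


class TestPartialCorrelationAndSimplify:
    def test_partial_correlation_limits(self):
        assert partial_correlation(0.0, 16) == 0.0
        assert partial_correlation(math.inf, 16, -1.0) == -1.0

    def test_partial_correlation_published_scale(self):
        # F = 14.2693 on 16 residual df: adopted formula gives ~0.687
        assert partial_correlation(14.2693, 16, 1.0) == pytest.approx(0.6866, abs=5e-4)

    def test_fitted_partial_r_bounded_and_signed(self):
        rng = np.random.default_rng(6)
        truth = random_quadratic(rng, 3)
        design = generate_ccd(truth.factors, n_center=5)
        y = truth.evaluate(design.coded) + rng.normal(0, 1, design.n_runs)
        a = fit(design.with_response(y)).anova
        assert np.all(np.abs(a.terms["partial_r"]) <= 1.0)

    def test_published_pvalues_drop_exactly_four_terms(self, ref_model):
        reduced, dropped = drop_insignificant(ref_model, TERM_PVALUES, alpha=0.10)
        assert sorted(dropped) == sorted(
            ["potassium_nitrate", "sodium_chloride", "potassium_nitrate^2",
             "peptone*potassium_nitrate"]
        )
        coef = reduced.coefficients()
        assert coef["b3"] == coef["b4"] == coef["b33"] == coef["b13"] == 0.0
        # retained coefficients keep their full-model values
        assert coef["b12"] == -6.05002 and coef["b0"] == 9.72944

    def test_alpha_one_keeps_full_model(self, ref_model):
        reduced, dropped = drop_insignificant(ref_model, TERM_PVALUES, alpha=1.0)
        assert dropped == [] and reduced.coefficients() == ref_model.coefficients()

    def test_alpha_zero_reduces_to_intercept(self, ref_model):
        reduced, dropped = drop_insignificant(ref_model, TERM_PVALUES, alpha=0.0)
        coef = reduced.coefficients()
        assert coef["b0"] == 9.72944
        assert all(v == 0.0 for k, v in coef.items() if k != "b0")
        assert len(dropped) == 14

    def test_simplify_from_fit_uses_fitted_pvalues(self):
        rng = np.random.default_rng(10)
        truth = QuadraticModel.from_coefficients(
            ["a", "b"], {"b0": 1.0, "b1": 50.0, "b11": -30.0}  # only two strong terms
        )
        design = generate_ccd(truth.factors, n_center=5)
        y = truth.evaluate(design.coded) + rng.normal(0, 0.5, design.n_runs)
        result = fit(design.with_response(y))
        reduced, dropped = simplify(result, alpha=0.01)
        kept = {k for k, v in reduced.coefficients().items() if v != 0.0}
        assert {"b0", "b1", "b11"} <= kept

    def test_main_effect_ranking_of_reference_model(self, ref_model):
        assert main_effect_ranking(ref_model) == [
            "peptone", "sucrose", "potassium_nitrate", "sodium_chloride"
        ]
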