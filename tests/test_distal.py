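import numpy as np
import pandas as pd
import pytest

from movetypes.distal import (
    ErrorMatrix,
    bch_distal_regression,
    bch_weights,
    classification_error_matrix,
    covariate_comparison,
    exp_coefficients,
    pool_rubin,
    school_variance_check,
)


class TestErrorMatrix:
    def test_crisp_posteriors_give_identity(self):
        post = np.eye(3)[np.array([0, 1, 2, 0, 1])]
        for mode in ("modal", "proportional"):
            D = classification_error_matrix(post, mode).d
            assert np.allclose(D, np.eye(3))

    def test_modal_formula_hand_example(self):
        post = np.array([[0.9, 0.1], [0.2, 0.8]])
        D = classification_error_matrix(post, "modal").d
        assert np.allclose(D, [[0.9 / 1.1, 0.2 / 1.1], [0.1 / 0.9, 0.8 / 0.9]],
                           atol=1e-4)
        assert np.allclose(D, [[0.8182, 0.1818], [0.1111, 0.8889]], atol=1e-4)

    def test_rows_sum_to_one_for_random_posteriors(self):
        rng = np.random.default_rng(0)
        post = rng.dirichlet(np.ones(3), size=50)
        for mode in ("modal", "proportional"):
            D = classification_error_matrix(post, mode).d
            assert np.allclose(D.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_class_rejected(self):
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            classification_error_matrix(post, "modal")


class TestBchWeights:
    def test_identity_error_returns_assignment_probabilities(self):
        rng = np.random.default_rng(1)
        post = rng.dirichlet(np.ones(2), size=20)
        err = ErrorMatrix(np.eye(2), "proportional")
        assert np.allclose(bch_weights(post, err).w, post)

    def test_hand_inverse_example_with_negative_weight(self):
        err = ErrorMatrix(np.array([[0.8, 0.2], [0.3, 0.7]]), "proportional")
        w = bch_weights(np.array([[0.9, 0.1]]), err).w
        assert np.allclose(w, [[1.20, -0.20]], atol=1e-9)
        assert w.sum() == pytest.approx(1.0)

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(2)
        post = rng.dirichlet(np.ones(3), size=100)
        err = classification_error_matrix(post, "proportional")
        w = bch_weights(post, err).w
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_column_sums_estimate_class_counts(self):
        rng = np.random.default_rng(3)
        # well-separated latent classes with known sizes
        truth = rng.random(2000) < 0.7
        noise = 0.15
        p1 = np.where(truth, 1 - noise, noise) + rng.normal(0, 0.03, 2000)
        p1 = np.clip(p1, 0.01, 0.99)
        post = np.column_stack([p1, 1 - p1])
        err = classification_error_matrix(post, "proportional")
        w = bch_weights(post, err).w
        assert w.sum(axis=0)[0] == pytest.approx(post[:, 0].sum(), rel=0.1)


class TestBchRegression:
    def test_crisp_classes_reduce_to_subgroup_mean_differences(self):
        rng = np.random.default_rng(4)
        n = 200
        cls = rng.integers(0, 2, n)
        y = 2.0 + 0.5 * cls + rng.standard_normal(n)
        post = np.eye(2)[cls]
        err = classification_error_matrix(post, "proportional")
        w = bch_weights(post, err)
        res = bch_distal_regression(y, w, log_outcome=False)
        expected = y[cls == 1].mean() - y[cls == 0].mean()
        assert res.coefficients[1] == pytest.approx(expected, abs=1e-9)
        assert res.coefficients[0] == pytest.approx(y[cls == 0].mean(), abs=1e-9)

    def test_negative_weights_complete_and_keep_row_sums(self):
        rng = np.random.default_rng(5)
        post = np.clip(rng.dirichlet([2, 2], size=100), 0.05, 0.95)
        post /= post.sum(axis=1, keepdims=True)
        err = ErrorMatrix(np.array([[0.75, 0.25], [0.3, 0.7]]), "proportional")
        w = bch_weights(post, err)
        assert (w.w < 0).any()
        res = bch_distal_regression(rng.uniform(1, 3, 100), w, log_outcome=True)
        assert np.all(np.isfinite(res.coefficients))
        assert np.allclose(w.w.sum(axis=1), 1.0, atol=1e-9)

    def test_log_transform_requires_positive_outcome(self):
        post = np.eye(2)[np.arange(10) % 2] * 0.8 + 0.1
        err = classification_error_matrix(post, "proportional")
        w = bch_weights(post, err)
        with pytest.raises(ValueError, match="log"):
            bch_distal_regression(np.linspace(-1, 5, 10), w, log_outcome=True)

    def test_ci_is_point_estimate_plus_minus_1p96_se(self):
        rng = np.random.default_rng(6)
        cls = rng.integers(0, 2, 150)
        post = np.eye(2)[cls] * 0.9 + 0.05
        err = classification_error_matrix(post, "proportional")
        w = bch_weights(post, err)
        res = bch_distal_regression(rng.uniform(1, 4, 150), w, log_outcome=True)
        assert np.allclose(res.ci95_low, res.coefficients - 1.96 * res.robust_se)
        assert np.allclose(res.ci95_high, res.coefficients + 1.96 * res.robust_se)


class TestExpCoefficients:
    def test_published_multipliers_from_log_coefficients(self):
        from movetypes.distal import DistalModelResult

        B = np.array([0.32, 0.36, 0.51, 0.13, 0.31, 0.0])
        res = DistalModelResult(
            outcome="fm_pct", log_transformed=True,
            terms=[f"t{i}" for i in range(6)], coefficients=B,
            robust_se=np.full(6, 0.1), ci95_low=B - 0.196, ci95_high=B + 0.196,
            p_value=np.full(6, 0.05),
        )
        table = exp_coefficients(res)
        assert table["exp_b"].tolist() == [1.38, 1.43, 1.67, 1.14, 1.36, 1.0]

    def test_ci_bounds_bracket_the_point_multiplier(self):
        from movetypes.distal import DistalModelResult

        res = DistalModelResult(
            outcome="vat", log_transformed=True, terms=["a"],
            coefficients=np.array([0.51]), robust_se=np.array([0.12]),
            ci95_low=np.array([0.51 - 1.96 * 0.12]),
            ci95_high=np.array([0.51 + 1.96 * 0.12]),
            p_value=np.array([0.03]),
        )
        row = exp_coefficients(res).iloc[0]
        assert row["exp_ci_low"] < row["exp_b"] < row["exp_ci_high"]

    def test_untransformed_outcome_rejected(self):
        from movetypes.distal import DistalModelResult

        res = DistalModelResult(
            outcome="bmi_z", log_transformed=False, terms=["a"],
            coefficients=np.array([0.1]), robust_se=np.array([0.1]),
            ci95_low=np.array([0.0]), ci95_high=np.array([0.2]),
            p_value=np.array([0.3]),
        )
        with pytest.raises(ValueError):
            exp_coefficients(res)


class TestCovariateComparison:
    def test_crisp_classes_match_plain_multinomial_logit(self):
        rng = np.random.default_rng(7)
        n = 400
        x = rng.standard_normal(n)
        logit = -0.3 + 1.2 * x
        cls = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        post = np.eye(2)[cls]
        err = classification_error_matrix(post, "modal")
        res = covariate_comparison(x, post, err)
        import statsmodels.api as sm

        ref = sm.Logit(cls, sm.add_constant(x)).fit(disp=0)
        assert res["coef"][1, 1] == pytest.approx(ref.params[1], rel=0.02)
        assert res["p"] < 1e-6

    def test_shifted_covariate_is_detected(self, children_fit, children_cohort):
        Z, model = children_fit
        rng = np.random.default_rng(8)
        x = rng.standard_normal(len(children_cohort)) + \
            children_cohort["true_class"].to_numpy()
        res = covariate_comparison(x, model.posteriors)
        assert res["p"] < 0.01


class TestSchoolCheck:
    def test_constant_outcome_gives_zero_icc(self):
        res = school_variance_check(np.ones(60), np.repeat(np.arange(6), 10))
        assert res["icc"] == 0.0

    def test_single_school_not_applicable(self):
        res = school_variance_check(np.random.default_rng(9).standard_normal(30),
                                    np.zeros(30))
        assert not res["applicable"]

    def test_equal_variance_components_give_icc_near_half(self):
        rng = np.random.default_rng(10)
        g = np.repeat(np.arange(100), 30)
        y = rng.standard_normal(100)[g] + rng.standard_normal(3000)
        res = school_variance_check(y, g)
        assert res["icc"] == pytest.approx(0.5, abs=0.1)
        assert res["lrt_p"] < 0.001

    def test_independent_outcome_rarely_flags_school(self):
        hits = 0
        for r in range(20):
            rng = np.random.default_rng(100 + r)
            y = rng.standard_normal(300)
            g = rng.integers(0, 11, 300)
            res = school_variance_check(y, g)
            hits += (res["icc"] >= 0.05) and (res["lrt_p"] < 0.05)
        assert hits <= 2


class TestRubinPooling:
    def test_single_imputation_has_no_between_variance(self):
        res = pool_rubin([1.5], [0.2])
        assert res.between_var == 0.0
        assert res.total_var == pytest.approx(0.2)

    def test_hand_example(self):
        res = pool_rubin([1.2, 1.4], [0.10, 0.10])
        assert res.estimate == pytest.approx(1.3)
        assert res.between_var == pytest.approx(0.02)
        assert res.total_var == pytest.approx(0.13)

    def test_identical_estimates_collapse_to_within_variance(self):
        res = pool_rubin([0.7, 0.7, 0.7], [0.05, 0.06, 0.07])
        assert res.between_var == pytest.approx(0.0, abs=1e-12)
        assert res.total_var == pytest.approx(0.06)
        assert res.df > 1e6  # effectively a normal reference

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([], [])
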