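import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from movetypes.composition import (
    build_basis,
    close,
    ilr_inverse_matrix,
    ilr_matrix,
    rotate_basis,
)
from movetypes.lpa import (
    FitDiagnostics,
    LPAModel,
    TypologyProfile,
    class_difference_table,
    compute_posteriors,
    diagnostics,
    fit_lpa,
    label_profiles,
    modal_assign,
    select_model,
    vlmr_test,
    weighted_descriptives,
)

COMP_COLS = ["mvpa_min", "lpa_min", "sb_min", "sleep_min"]


def _two_component_data(n=400, sep=3.0, seed=0, d=3):
    rng = np.random.default_rng(seed)
    cls = rng.integers(0, 2, n)
    means = np.zeros((2, d))
    means[0, 0], means[1, 0] = -sep, sep
    return means[cls] + rng.standard_normal((n, d)), cls


class TestFit:
    def test_single_class_is_the_closed_form_gaussian(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3)) * [1.0, 2.0, 0.5]
        m = fit_lpa(X, K=1)
        assert np.allclose(m.means[0], X.mean(axis=0))
        assert np.allclose(m.shared_cov, np.cov(X.T, bias=True))
        assert np.allclose(m.posteriors, 1.0)
        assert m.n_params == 0 + 3 + 6

    def test_recovers_two_separated_components(self):
        X, truth = _two_component_data(seed=1)
        m = fit_lpa(X, K=2, n_starts=10, seed=2)
        order = np.argsort(m.means[:, 0])
        assert np.allclose(m.means[order, 0], [-3.0, 3.0], atol=0.2)
        assert np.allclose(np.sort(m.mixing), np.sort(np.bincount(truth) / 400), atol=0.05)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, modal_assign(m.posteriors)) > 0.95

    def test_loglik_trace_is_nondecreasing(self):
        X, _ = _two_component_data(sep=1.0, seed=3)
        m = fit_lpa(X, K=2, n_starts=5, seed=4)
        assert np.all(np.diff(m.loglik_trace) >= -1e-8)

    def test_matches_sklearn_tied_mixture_likelihood(self):
        from sklearn.mixture import GaussianMixture

        X, _ = _two_component_data(n=300, sep=2.0, seed=5)
        ours = fit_lpa(X, K=2, n_starts=20, seed=6)
        ref = GaussianMixture(
            n_components=2, covariance_type="tied", n_init=10, reg_covar=1e-10,
            tol=1e-8, max_iter=1000, random_state=0,
        ).fit(X)
        assert ours.loglik == pytest.approx(ref.score(X) * len(X), rel=1e-4)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_lpa(np.zeros((5, 3)), K=2)


class TestPosteriors:
    def test_equidistant_point_splits_evenly(self):
        mix = np.array([0.5, 0.5])
        means = np.array([[-1.0, 0.0], [1.0, 0.0]])
        post = compute_posteriors(mix, means, np.eye(2), np.array([[0.0, 5.0]]))
        assert np.allclose(post, 0.5)

    def test_point_at_a_separated_mean_is_assigned_there(self):
        mix = np.array([0.5, 0.5])
        means = np.array([[-4.0, 0.0], [4.0, 0.0]])
        post = compute_posteriors(mix, means, np.eye(2), means[1][None, :])
        assert post[0, 1] > 0.99

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        post = compute_posteriors(
            np.array([0.3, 0.7]), rng.standard_normal((2, 3)), np.eye(3),
            rng.standard_normal((50, 3)),
        )
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_brute_force_oracle_on_tiny_sample(self):
        # independent route: scipy densities, direct normalisation
        # (2 coordinates so the 2-class model stays identifiable at n=12)
        rng = np.random.default_rng(8)
        X = rng.standard_normal((12, 2))
        m = fit_lpa(X, K=2, n_starts=5, seed=9, max_iter=50)
        dens = np.column_stack([
            m.mixing[k] * multivariate_normal.pdf(X, m.means[k], m.shared_cov)
            for k in range(2)
        ])
        oracle = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(m.posteriors, oracle, atol=1e-9)


class TestDiagnostics:
    def test_information_criteria_formulas(self):
        m = LPAModel(K=2, mixing=np.array([0.5, 0.5]), means=np.zeros((2, 3)),
                     shared_cov=np.eye(3), loglik=150.0,
                     posteriors=np.full((374, 2), 0.5), converged=True,
                     n_params=13)
        d = diagnostics(m, n=374)
        assert d.bic == pytest.approx(-222.98, abs=0.01)
        assert d.aic == pytest.approx(-274.0, abs=0.01)

    def test_entropy_bounds_and_hand_value(self):
        base = dict(K=2, mixing=np.array([0.5, 0.5]), means=np.zeros((2, 3)),
                    shared_cov=np.eye(3), loglik=0.0, converged=True, n_params=13)
        crisp = diagnostics(LPAModel(posteriors=np.eye(2), **base), n=2)
        uniform = diagnostics(
            LPAModel(posteriors=np.full((2, 2), 0.5), **base), n=2)
        hand = diagnostics(
            LPAModel(posteriors=np.array([[0.9, 0.1], [0.9, 0.1]]), **base), n=2)
        assert crisp.entropy == pytest.approx(1.0)
        assert uniform.entropy == pytest.approx(0.0, abs=1e-12)
        assert hand.entropy == pytest.approx(0.53101, abs=1e-5)

    def test_min_class_share_is_smallest_expected_share(self):
        post = np.array([[0.9, 0.1]] * 10)
        m = LPAModel(K=2, mixing=np.array([0.9, 0.1]), means=np.zeros((2, 3)),
                     shared_cov=np.eye(3), loglik=0.0, posteriors=post,
                     converged=True, n_params=13)
        assert diagnostics(m).min_class_share == pytest.approx(0.1)


class TestVlmr:
    def test_identical_models_give_p_one(self):
        X, _ = _two_component_data(seed=10)
        m1 = fit_lpa(X, K=1)
        m1b = LPAModel(K=2, mixing=np.array([0.5, 0.5]),
                       means=np.vstack([m1.means, m1.means]),
                       shared_cov=m1.shared_cov, loglik=m1.loglik,
                       posteriors=np.full((len(X), 2), 0.5), converged=True,
                       n_params=m1.n_params + 4)
        assert vlmr_test(m1b, m1, len(X)) == 1.0

    def test_separated_components_are_detected(self):
        X, _ = _two_component_data(n=400, sep=3.0, seed=11)
        m1 = fit_lpa(X, K=1)
        m2 = fit_lpa(X, K=2, n_starts=10, seed=12)
        assert vlmr_test(m2, m1, 400, mode="lmr_adjusted") < 0.01
        assert vlmr_test(m2, m1, 400, mode="bootstrap", z_matrix=X, B=19,
                         seed=13) <= 0.05

    def test_wrong_class_gap_rejected(self):
        X, _ = _two_component_data(seed=14)
        m1 = fit_lpa(X, K=1)
        m3 = fit_lpa(X, K=3, n_starts=5, seed=15)
        with pytest.raises(ValueError):
            vlmr_test(m3, m1, len(X))


class TestAssignmentAndProfiles:
    @pytest.mark.parametrize(
        "row,expected",
        [((0.6, 0.4), 0), ((0.5, 0.5), 0), ((0.1, 0.2, 0.7), 2)],
    )
    def test_modal_assignment_with_low_index_ties(self, row, expected):
        assert modal_assign(np.array([row]))[0] == expected

    def test_crisp_posteriors_reduce_to_subgroup_statistics(self):
        rng = np.random.default_rng(16)
        records = pd.DataFrame({
            "age": rng.uniform(8, 13, 20),
            "sex_girl": rng.integers(0, 2, 20).astype(float),
            "mvpa_min": rng.uniform(30, 90, 20),
            "lpa_min": rng.uniform(250, 350, 20),
            "sb_min": rng.uniform(500, 640, 20),
            "sleep_min": rng.uniform(480, 560, 20),
        })
        post = np.zeros((20, 2))
        post[:12, 0] = 1.0
        post[12:, 1] = 1.0
        profiles = weighted_descriptives(records, post, continuous=["age"],
                                         binary=["sex_girl"])
        sub = records.iloc[:12]
        stats0 = profiles[0].weighted_stats.set_index("variable")
        assert stats0.loc["age", "mean"] == pytest.approx(sub["age"].mean())
        assert stats0.loc["age", "sd"] == pytest.approx(sub["age"].std(ddof=1))
        assert stats0.loc["sex_girl", "mean"] == pytest.approx(sub["sex_girl"].mean())

    def test_uniform_posteriors_reproduce_overall_mean(self):
        rng = np.random.default_rng(17)
        records = pd.DataFrame({
            "age": rng.uniform(8, 13, 30),
            "mvpa_min": rng.uniform(30, 90, 30),
            "lpa_min": rng.uniform(250, 350, 30),
            "sb_min": rng.uniform(500, 640, 30),
            "sleep_min": rng.uniform(480, 560, 30),
        })
        post = np.full((30, 2), 0.5)
        profiles = weighted_descriptives(records, post, continuous=["age"])
        for p in profiles:
            assert p.weighted_stats.loc[0, "mean"] == pytest.approx(records["age"].mean())

    def test_zero_weight_rows_are_ignored_in_the_mean(self):
        records = pd.DataFrame({
            "age": [1.0, 2.0, 3.0],
            "mvpa_min": [60.0] * 3, "lpa_min": [300.0] * 3,
            "sb_min": [560.0] * 3, "sleep_min": [520.0] * 3,
        })
        post = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        profiles = weighted_descriptives(records, post, continuous=["age"])
        assert profiles[0].weighted_stats.loc[0, "mean"] == pytest.approx(2.0)


def _profiles_from_minutes(rows, labels=None):
    out = []
    for i, row in enumerate(rows):
        out.append(TypologyProfile(
            label=labels[i] if labels else f"class{i + 1}",
            share=1.0 / len(rows),
            compositional_mean=close(row),
        ))
    return out


class TestLabelsAndDifferences:
    def test_two_class_labels_follow_mvpa_ordering(self):
        profiles = _profiles_from_minutes(
            [(31.4, 259.9, 621.2, 527.5), (63.7, 310.5, 547.6, 518.2)])
        labelled = label_profiles(profiles)
        assert [p.label for p in labelled] == ["Workers", "Queens"]
        assert labelled[0].compositional_mean.values[0] == pytest.approx(63.7, abs=0.1)

    def test_three_class_solution_gets_drones_in_the_middle(self):
        profiles = _profiles_from_minutes([
            (16.6, 231.5, 734.9, 457.0),
            (56.2, 255.9, 658.6, 469.3),
            (31.7, 248.6, 687.4, 472.3),
        ])
        assert [p.label for p in label_profiles(profiles)] == \
            ["Workers", "Drones", "Queens"]

    def test_single_class_defaults_to_workers(self):
        profiles = _profiles_from_minutes([(60.0, 300.0, 560.0, 520.0)])
        assert label_profiles(profiles)[0].label == "Workers"

    def test_children_difference_table_matches_published_contrasts(self):
        labelled = label_profiles(_profiles_from_minutes(
            [(63.7, 310.5, 547.6, 518.2), (31.4, 259.9, 621.2, 527.5)]))
        table = class_difference_table(labelled)
        wq = table[(table["profile"] == "Workers") & (table["versus"] == "Queens")]
        got = dict(zip(wq["behaviour"], wq["difference_min"]))
        assert got == {"mvpa": 32.3, "lpa": 50.6, "sb": -73.6, "sleep": -9.3}

    def test_profile_against_itself_differs_by_zero(self):
        labelled = label_profiles(_profiles_from_minutes(
            [(63.7, 310.5, 547.6, 518.2), (31.4, 259.9, 621.2, 527.5)]))
        table = class_difference_table([labelled[0], labelled[0]])
        assert (table["difference_min"] == 0.0).all()


def _diag(K, bic, min_share, vlmr_p=None):
    return FitDiagnostics(K=K, loglik=0.0, n_params=0, bic=bic, aic=bic,
                          entropy=0.6, min_class_share=min_share, vlmr_p=vlmr_p)


class TestSelection:
    def test_small_class_solutions_are_excluded(self):
        fits = {2: _diag(2, bic=-233.0, min_share=0.195),
                3: _diag(3, bic=-240.0, min_share=0.047)}
        sel = select_model(fits)
        assert sel.K == 2
        assert any("K=3 excluded" in note for note in sel.rationale)

    def test_lowest_bic_wins_among_passing_candidates(self):
        fits = {1: _diag(1, bic=-100.0, min_share=1.0),
                2: _diag(2, bic=-233.0, min_share=0.195),
                3: _diag(3, bic=-217.2, min_share=0.107)}
        assert select_model(fits).K == 2

    def test_vlmr_gate_blocks_unsupported_models_when_enabled(self):
        fits = {1: _diag(1, bic=-100.0, min_share=1.0),
                2: _diag(2, bic=-233.0, min_share=0.195, vlmr_p=0.40)}
        assert select_model(fits, use_vlmr_gate=True).K == 1
        assert select_model(fits, use_vlmr_gate=False).K == 2

    def test_single_passing_candidate_is_chosen(self):
        fits = {2: _diag(2, bic=-233.0, min_share=0.195)}
        assert select_model(fits).K == 2

    def test_no_passing_candidate_raises(self):
        fits = {2: _diag(2, bic=-233.0, min_share=0.01)}
        with pytest.raises(RuntimeError):
            select_model(fits)


class TestBasisInvariance:
    def test_fit_is_invariant_to_the_ilr_basis(self, children_cohort):
        # mixture on coordinates from two orthonormal bases: same likelihood
        # and posteriors (the bases are mutual rotations)
        basis = build_basis(4)
        rng = np.random.default_rng(18)
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        other = rotate_basis(basis, Q)
        X = children_cohort[COMP_COLS].to_numpy()[:150]
        Z1 = ilr_matrix(X, basis)
        Z2 = ilr_matrix(X, other)
        m1 = fit_lpa(Z1, K=2, n_starts=20, seed=19)
        m2 = fit_lpa(Z2, K=2, n_starts=20, seed=20)
        assert m1.loglik == pytest.approx(m2.loglik, abs=1e-6 * abs(m1.loglik) + 1e-6)
        # rotate m1's parameters into the second basis: posteriors must agree
        post = compute_posteriors(m1.mixing, m1.means @ Q, Q.T @ m1.shared_cov @ Q, Z2)
        order = np.argsort(post.mean(axis=0))
        order2 = np.argsort(m2.posteriors.mean(axis=0))
        assert np.allclose(post[:, order], m2.posteriors[:, order2], atol=1e-5)
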