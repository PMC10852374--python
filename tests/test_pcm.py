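"""Partial credit model: probabilities, estimation, thresholds, collapsing."""

import itertools

import numpy as np
import pytest

from quickrasch.pcm import (PartialCreditModel, andrich_thresholds,
                            auto_collapse, category_probs)
from quickrasch.response import DataError, ResponseMatrix


class TestCategoryProbs:
    def test_flat_steps_give_uniform_at_zero(self):
        np.testing.assert_allclose(category_probs(0.0, [0, 0, 0, 0]),
                                   np.full(5, 0.2), atol=1e-12)

    def test_dichotomous_rasch_at_ability_equals_difficulty(self):
        np.testing.assert_allclose(category_probs(0.0, [0.0]), [0.5, 0.5])

    def test_hand_computed_three_category_case(self):
        # cumulative logits at theta=1, delta=(0.5, 1.5): (0, 0.5, 0.0)
        p = category_probs(1.0, [0.5, 1.5])
        np.testing.assert_allclose(p, [0.2741, 0.4519, 0.2741], atol=5e-5)

    @pytest.mark.parametrize("theta", np.linspace(-6, 6, 13))
    def test_probabilities_sum_to_one(self, theta):
        p = category_probs(theta, [-1.2, 0.3, 2.0])
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_expected_score_strictly_increasing_in_theta(self):
        grid = np.linspace(-6, 6, 121)
        p = category_probs(grid, [-1.0, 0.0, 1.0, 2.5])
        escore = p @ np.arange(5)
        assert np.all(np.diff(escore) > 0)


class TestFit:
    def test_parameter_recovery(self, calib_matrix, standard_deltas, calib_fit):
        est = np.concatenate(calib_fit.step_difficulties_)
        true = np.concatenate(standard_deltas)
        rmse = np.sqrt(np.mean((est - true) ** 2))
        assert calib_fit.converged_
        assert rmse <= 0.1
        assert calib_fit.prior_sd_ == pytest.approx(1.0, abs=0.1)

    def test_loglik_non_decreasing(self, calib_fit):
        assert np.all(np.diff(calib_fit.loglik_path_) >= -1e-8)

    def test_duplicated_sample_gives_identical_estimates(self, cts_matrix):
        half = cts_matrix.values[:400]
        double = np.vstack([half, half])
        f1 = PartialCreditModel().fit(half)
        f2 = PartialCreditModel().fit(double)
        np.testing.assert_allclose(
            np.concatenate(f1.step_difficulties_),
            np.concatenate(f2.step_difficulties_), atol=1e-6)
        assert f1.prior_sd_ == pytest.approx(f2.prior_sd_, abs=1e-6)

    def test_loglik_at_optimum_beats_generating_parameters(
            self, calib_matrix, standard_deltas, calib_fit):
        truth = PartialCreditModel.from_parameters(standard_deltas, prior_sd=1.0)
        assert calib_fit.log_likelihood(calib_matrix) >= \
            truth.log_likelihood(calib_matrix) - 1e-6

    def test_unobserved_category_raises_with_recode_hint(self):
        X = np.array([[0, 0], [2, 1], [2, 2]])  # category 1 of item 1 unseen
        with pytest.raises(DataError, match="recode"):
            PartialCreditModel().fit(X)

    def test_fixed_prior_sd_stays_fixed(self, cts_matrix):
        f = PartialCreditModel(estimate_prior_sd=False, prior_sd=1.0,
                               max_cycles=50).fit(cts_matrix.values[:300])
        assert f.prior_sd_ == 1.0

    def test_sklearn_param_interface(self):
        est = PartialCreditModel(tol=1e-3)
        assert est.get_params()["tol"] == 1e-3
        est.set_params(max_cycles=10)
        assert est.max_cycles == 10


class TestEAP:
    def test_posterior_symmetry_gives_zero_eap_at_middle_sum(self):
        fit = PartialCreditModel.from_parameters(
            [np.array([-1.0, 1.0]), np.array([-0.5, 0.5])], prior_sd=1.0)
        # middle internal sum = 2; e.g. pattern (1, 1)
        eap = fit.eap_scores(np.array([[1, 1]]))["eap"][0]
        assert eap == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_response_severity(self, toy_fit):
        scores = toy_fit.eap_scores(np.array([[0, 0], [2, 2]]))["eap"]
        assert scores[0] < scores[1]

    def test_matches_refined_quadrature_oracle(self, toy_fit):
        fine = PartialCreditModel.from_parameters(
            toy_fit.step_difficulties_, prior_sd=toy_fit.prior_sd_,
            n_quadrature=610)
        patterns = np.array(list(itertools.product(range(3), range(3))))
        coarse = toy_fit.eap_scores(patterns)["eap"]
        refined = fine.eap_scores(patterns)["eap"]
        np.testing.assert_allclose(coarse, refined, atol=1e-3)

    def test_sum_score_sufficiency_exhaustive(self):
        fit = PartialCreditModel.from_parameters(
            [np.array([-0.8, 0.3]), np.array([0.1]), np.array([-0.4, 1.2])])
        patterns = np.array(list(itertools.product(range(3), range(2), range(3))))
        eap = fit.eap_scores(patterns)["eap"].to_numpy()
        sums = patterns.sum(axis=1)
        for s in np.unique(sums):
            grp = eap[sums == s]
            assert np.ptp(grp) < 1e-12

    def test_se_positive_and_transform_shape(self, toy_fit):
        out = toy_fit.transform(np.array([[0, 0], [1, 2]]))
        assert out.shape == (2, 2)
        assert np.all(out[:, 1] > 0)


class TestThresholds:
    def test_ordered_thresholds_have_no_flags(self):
        fit = PartialCreditModel.from_parameters([np.array([-2., -1., 0., 1.])])
        rep = andrich_thresholds(fit, tol=0.2)
        assert not rep.any_flags
        assert rep.merges == [None]

    def test_disorder_flagged_on_reversed_top_step(self):
        fit = PartialCreditModel.from_parameters([np.array([-2., -1., 1., 0.5])])
        rep = andrich_thresholds(fit, tol=0.2)
        assert rep.disordered[0] == [2]
        assert rep.merges[0] == (3, 4)  # merge the two worst options

    def test_closeness_flagged_within_tolerance(self):
        fit = PartialCreditModel.from_parameters([np.array([-1.0, -0.9, 1.0])])
        rep = andrich_thresholds(fit, tol=0.2)
        assert rep.close[0] == [0]
        assert rep.disordered[0] == []
        assert rep.merges[0] == (1, 2)

    def test_tie_breaks_toward_most_severe_categories(self):
        fit = PartialCreditModel.from_parameters([np.array([0.5, 0.0, 1.0, 0.5])])
        rep = andrich_thresholds(fit, tol=0.2)
        # gaps (-0.5, 1.0, -0.5): tie between gap 0 and gap 2
        assert rep.merges[0] == (3, 4)

    def test_disorder_detected_on_dupuytren_like_fixture(self, dupuytren_matrix):
        fit = PartialCreditModel().fit(dupuytren_matrix)
        rep = andrich_thresholds(fit, tol=0.2)
        top_flagged = sum(1 for mg in rep.merges if mg == (3, 4))
        assert top_flagged >= 5


class TestAutoCollapse:
    def test_ordered_data_returns_identity(self, cts_matrix):
        recode, fit, rep = auto_collapse(cts_matrix)
        assert recode.is_identity()
        assert not rep.any_flags

    def test_dupuytren_fixture_merges_worst_options(self, dupuytren_collapse):
        recode, fit, rep = dupuytren_collapse
        merged = [item for item, m in recode.maps.items() if m == [0, 1, 2, 3, 3]]
        assert len(merged) >= 5

    def test_no_flags_after_collapse(self, dupuytren_collapse):
        _, _, rep = dupuytren_collapse
        assert not rep.any_flags

    def test_collapse_bounded_by_category_budget(self):
        # pathological: 3-category item with persistent disorder cannot be
        # merged below 2 categories
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(300, 2))
        recode, fit, rep = auto_collapse(
            ResponseMatrix(X, ["a", "b"], np.array([3, 3])))
        assert all(max(m) + 1 >= 2 for m in recode.maps.values())


def test_icc_table_long_format(toy_fit):
    df = toy_fit.icc_table(n_grid=5)
    assert set(df.columns) == {"theta", "item", "category", "probability"}
    total = df.groupby(["item", "theta"])["probability"].sum()
    np.testing.assert_allclose(total, 1.0, atol=1e-12)
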