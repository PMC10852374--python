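"""Item fit, local dependence, scale indices and targeting diagnostics."""

import numpy as np
import pytest

from quickrasch import diagnostics as dg
from quickrasch.pcm import PartialCreditModel, category_probs
from quickrasch.simulate import SimSpec, inject_ld, simulate

DELTAS = tuple(tuple(np.array([-1.5, -0.5, 0.5, 1.5]) + c)
               for c in np.linspace(-1, 1, 6))


def _simulate_with_theta(n, deltas, seed, transform=None):
    """Direct PCM draws returning (X, theta) for injection designs."""
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, n)
    X = np.empty((n, len(deltas)), dtype=int)
    for j, d in enumerate(deltas):
        p = category_probs(theta, np.asarray(d))
        X[:, j] = (p.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
    if transform is not None:
        X = transform(X, theta, rng)
    return X, theta


class TestStandardizedResiduals:
    def test_mean_near_zero_under_model(self, calib_fit, calib_matrix):
        z = dg.standardized_residuals(calib_fit, calib_matrix)
        assert abs(np.nanmean(z)) < 0.05

    def test_dichotomous_unit_residual(self):
        fit = PartialCreditModel.from_parameters([np.array([0.0])])
        z = dg.standardized_residuals(fit, np.array([[1]]), method="plugin",
                                      scores={"eap": np.array([0.0])})
        # P = 0.5 at theta 0: z = (1 - 0.5) / 0.5 = 1
        assert z[0, 0] == pytest.approx(1.0)

    def test_response_at_model_expectation_has_small_residual(self, toy_fit):
        z = dg.standardized_residuals(toy_fit, np.array([[1, 1]]))
        assert np.all(np.abs(z) < 1.0)


class TestInfitOutfit:
    def test_calibrated_under_model(self, calib_fit, calib_matrix):
        res = dg.infit_outfit(calib_fit, calib_matrix)
        assert np.all((res.outfit > 0.5) & (res.outfit < 1.7))
        assert np.all((res.infit > 0.5) & (res.infit < 1.7))
        assert abs(res.outfit.mean() - 1) < 0.15
        assert abs(res.infit.mean() - 1) < 0.15
        assert not res.flagged

    def test_noise_item_trips_outfit(self):
        def noisy(X, theta, rng):
            X[:, 0] = rng.integers(0, 5, len(X))
            return X
        X, _ = _simulate_with_theta(1000, DELTAS, 42, noisy)
        fit = PartialCreditModel().fit(X)
        res = dg.infit_outfit(fit, X)
        assert res.outfit[0] > 1.7
        assert fit.item_ids_[0] in res.flagged

    def test_deterministic_item_pair_deflates_plugin_infit(self):
        def guttman(X, theta, rng):
            X[:, 0] = np.digitize(theta, DELTAS[0])
            X[:, 1] = np.digitize(theta, DELTAS[1])
            return X
        X, _ = _simulate_with_theta(1000, DELTAS, 42, guttman)
        fit = PartialCreditModel().fit(X)
        res = dg.infit_outfit(fit, X, method="plugin")
        assert res.infit[0] < 0.5 and res.infit[1] < 0.5

    def test_replicate_medians_near_one(self, standard_deltas):
        """Across replicates under the generating model, per-item median
        mean squares stay in [0.9, 1.1] (statistic evaluated at the known
        parameters; 200 cohorts)."""
        fit = PartialCreditModel.from_parameters(standard_deltas)
        infits, outfits = [], []
        for rep in range(200):
            m = simulate(SimSpec(n=250, delta=DELTAS, seed=20_000 + rep))
            r = dg.infit_outfit(fit, m)
            infits.append(r.infit)
            outfits.append(r.outfit)
        med_in = np.median(infits, axis=0)
        med_out = np.median(outfits, axis=0)
        assert np.all((med_in > 0.9) & (med_in < 1.1))
        assert np.all((med_out > 0.9) & (med_out < 1.1))


class TestItemChisq:
    def test_type_one_error_calibrated(self, standard_deltas):
        """Rejection rate at alpha = 0.05 over model-consistent replicates
        stays within [0.02, 0.10] (statistic at known parameters)."""
        fit = PartialCreditModel.from_parameters(standard_deltas)
        rej = tot = 0
        for rep in range(150):
            m = simulate(SimSpec(n=500, delta=DELTAS, seed=30_000 + rep))
            res = dg.item_chisq(fit, m)
            ok = ~np.isnan(res.p_value)
            rej += int(np.sum(res.p_value[ok] < 0.05))
            tot += int(ok.sum())
        assert 0.02 <= rej / tot <= 0.10

    def test_steep_slope_item_detected_at_large_n(self):
        def steep(X, theta, rng):
            # 2-parameter-style item: discrimination 3 inside a Rasch fit
            p = category_probs(3.0 * theta, np.asarray(DELTAS[0]) * 3.0)
            X[:, 0] = (p.cumsum(axis=1) < rng.random((len(X), 1))).sum(axis=1)
            return X
        X, _ = _simulate_with_theta(2000, DELTAS, 9, steep)
        fit = PartialCreditModel().fit(X)
        res = dg.item_chisq(fit, X)
        assert res.p_value[0] < 0.01

    def test_reports_df_and_p_in_range(self, calib_fit, calib_matrix):
        res = dg.item_chisq(calib_fit, calib_matrix)
        assert np.all(res.df[~np.isnan(res.df)] >= 1)
        ok = ~np.isnan(res.p_value)
        assert np.all((res.p_value[ok] >= 0) & (res.p_value[ok] <= 1))


class TestQ3:
    def test_independent_items_below_cutoff(self, calib_fit, calib_matrix):
        z = dg.standardized_residuals(calib_fit, calib_matrix)
        res = dg.q3_matrix(z)
        assert np.nanmax(res.Q3) <= 0.2
        assert not res.flagged_pairs

    def test_testlet_pair_flagged(self):
        spec = inject_ld(SimSpec(n=2000, delta=DELTAS, seed=11), (1, 2), 1.5)
        m = simulate(spec)
        fit = PartialCreditModel().fit(m)
        z = dg.standardized_residuals(fit, m)
        res = dg.q3_matrix(z, fit.item_ids_)
        assert res.flagged_pairs == [("item2", "item3")]

    def test_orthogonal_residuals_give_zero(self):
        z = np.array([[1., 1.], [1., -1.], [-1., 1.], [-1., -1.]])
        res = dg.q3_matrix(z)
        assert res.Q3[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, calib_fit, calib_matrix):
        z = dg.standardized_residuals(calib_fit, calib_matrix)
        Q3 = dg.q3_matrix(z).Q3
        np.testing.assert_allclose(Q3, Q3.T)


class TestCronbachAlpha:
    def test_closed_form_two_items(self):
        # variances 1, covariance 0.5 -> alpha = 2 * (1 - 2/3) = 2/3
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=200_000)
        alpha = dg.cronbach_alpha(np.round(z * 10).astype(int))
        assert alpha == pytest.approx(2 / 3, abs=0.01)

    def test_two_item_oracle_exact(self):
        X = np.array([[0, 1], [1, 3], [2, 2], [4, 4], [3, 0], [2, 3]])
        v = X.var(axis=0, ddof=1).sum()
        tot = X.sum(axis=1).var(ddof=1)
        assert dg.cronbach_alpha(X) == pytest.approx(2 * (1 - v / tot), abs=1e-12)

    def test_identical_columns_give_one(self):
        x = np.array([0, 1, 2, 3, 2, 1])
        assert dg.cronbach_alpha(np.column_stack([x] * 4)) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, (50_000, 4))
        assert abs(dg.cronbach_alpha(X)) < 0.02


class TestScaleFit:
    def test_model_consistent_data_passes_index_rules(self, calib_fit,
                                                      calib_matrix):
        res = dg.scale_fit_indices(calib_fit, calib_matrix)
        assert res.rmsea < 0.060
        assert res.cfi >= 0.950
        assert res.tli >= 0.950
        assert res.srmr <= 0.080
        assert 0.7 < res.alpha < 0.95

    def test_two_dimensional_data_violates_indices(self):
        def twodim(X, theta, rng):
            other = rng.normal(0, 1, len(X))
            for j in range(3, 6):
                p = category_probs(other, np.asarray(DELTAS[j]))
                X[:, j] = (p.cumsum(axis=1) < rng.random((len(X), 1))).sum(axis=1)
            return X
        X, _ = _simulate_with_theta(2000, DELTAS, 11, twodim)
        fit = PartialCreditModel().fit(X)
        res = dg.scale_fit_indices(fit, X)
        assert not all(v for k, v in res.passes().items() if k != "chisq")

    def test_saturated_residual_gives_zero_chisq(self):
        sigma = np.eye(4)
        T, rank = dg._quadratic_form(np.zeros(4), sigma, 1000)
        assert T == 0.0
        assert rank == 4

    def test_invariants(self, calib_fit, calib_matrix):
        res = dg.scale_fit_indices(calib_fit, calib_matrix)
        assert res.rmsea >= 0
        assert res.cfi <= 1 and res.tli <= 1
        assert 0 <= res.p_value <= 1


class TestOptionCurves:
    def test_smoothed_curves_track_model(self, calib_fit, calib_matrix):
        scores = calib_fit.eap_scores(calib_matrix)
        df = dg.empirical_option_curves(calib_fit, calib_matrix, scores)
        theta = scores["eap"]
        lo, hi = np.quantile(theta, [0.1, 0.9])
        central = df[(df.theta >= lo) & (df.theta <= hi)]
        assert np.max(np.abs(central.observed - central.expected)) < 0.05

    def test_constant_trait_estimates_error(self, toy_fit):
        with pytest.raises(ValueError, match="identical"):
            dg.empirical_option_curves(
                toy_fit, np.array([[1, 1]] * 5),
                scores={"eap": np.zeros(5)})

    def test_mistargeted_item_top_option_stays_near_zero(self, dupuytren_matrix):
        fit = PartialCreditModel().fit(dupuytren_matrix)
        scores = fit.eap_scores(dupuytren_matrix)
        df = dg.empirical_option_curves(fit, dupuytren_matrix, scores)
        hardest = fit.item_ids_[-1]
        top = df[(df.item == hardest)
                 & (df.category == df[df.item == hardest].category.max())]
        assert np.nanmax(top.observed) < 0.25


class TestItemPersonMap:
    def test_well_targeted_fixture_has_small_gap(self, calib_fit, calib_matrix):
        scores = calib_fit.eap_scores(calib_matrix)
        ipm = dg.item_person_map(calib_fit, scores)
        assert abs(ipm["targeting_gap"]) < 0.1

    def test_dupuytren_fixture_is_negatively_skewed_and_mistargeted(
            self, dupuytren_matrix):
        fit = PartialCreditModel().fit(dupuytren_matrix)
        scores = fit.eap_scores(dupuytren_matrix)
        ipm = dg.item_person_map(fit, scores)
        assert ipm["skewness"] < -0.3
        assert ipm["threshold_mean"] > ipm["person_mean"]

    def test_single_person_histogram(self, toy_fit):
        scores = toy_fit.eap_scores(np.array([[1, 1]]))
        ipm = dg.item_person_map(toy_fit, scores, n_bins=5)
        assert sum(ipm["histogram"]["counts"]) == 1
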