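"""Feature-space normalization, fits, and classifier machinery."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import meshcurv as mc


def brute_force_accuracy(clf, X, y):
    """Independent per-row prediction count."""
    pred = clf.predict(X)
    return sum(p == t for p, t in zip(pred, y)) / len(y)


@pytest.fixture(scope="module")
def cohort():
    return mc.simulate_feature_cohort(mc.CohortSpec(seed=5))


@pytest.fixture(scope="module")
def norm_cohort(cohort):
    table, _ = mc.normalize(cohort)
    return table


class TestNormalize:
    def test_constant_normal_group_maps_to_one(self):
        table = pd.DataFrame(
            {"group": ["normal"] * 5, "delta_K": [2.0] * 5, "ell": [10.0] * 5}
        )
        out, consts = mc.normalize(table)
        assert (out["delta_K_tilde"] == 1.0).all()
        assert (out["ell_tilde_inv"] == 1.0).all()
        assert consts.delta_K_norm == 2.0

    def test_triple_baseline_maps_to_three(self):
        table = pd.DataFrame(
            {
                "group": ["normal", "normal", "failed"],
                "delta_K": [1.0, 1.0, 3.0],
                "ell": [10.0, 10.0, 20.0],
            }
        )
        out, _ = mc.normalize(table)
        assert out.loc[2, "delta_K_tilde"] == pytest.approx(3.0)
        assert out.loc[2, "ell_tilde_inv"] == pytest.approx(0.5)

    def test_constants_transfer_to_held_out_cohort(self):
        _, consts = mc.normalize(mc.simulate_feature_cohort(mc.CohortSpec(seed=1)))
        held_out = mc.simulate_feature_cohort(mc.CohortSpec(seed=2))
        out = consts.apply(held_out)
        mean_norm = out[out.group == "normal"]["delta_K_tilde"].mean()
        assert mean_norm == pytest.approx(1.0, abs=0.1)

    def test_missing_normal_group_rejected(self):
        table = pd.DataFrame({"group": ["failed"], "delta_K": [1.0], "ell": [1.0]})
        with pytest.raises(ValueError):
            mc.normalize(table)


@pytest.fixture(scope="module")
def tube_table():
    rows = []
    for radius in (6.0, 9.0, 12.0):
        spec = mc.TubeSpec(radius=radius, bump_amplitude=0.0, seed=0)
        feats = mc.specimen_pipeline(
            mc.generate_tube(spec), mc.PipelineConfig.light(0)
        )
        row = feats.to_row()
        row["centerline_length"] = spec.length
        rows.append(row)
    return pd.DataFrame(rows)


class TestScalingFits:
    def test_construction_ratio_recovered(self, tube_table):
        out = mc.size_scaling_fit(tube_table)
        assert out["c_mean"] == pytest.approx(16.6, rel=0.02)

    def test_area_prefactor_matches_generalized_cylinder(self, tube_table):
        out = mc.size_scaling_fit(tube_table)
        # A_T ~ 2*pi*c*ell^2 for smooth tubes
        assert out["c_from_area"] == pytest.approx(16.6, rel=0.1)

    def test_degenerate_table_rejected(self, tube_table):
        with pytest.raises(ValueError):
            mc.size_scaling_fit(tube_table.iloc[:1])


class TestDistributionFits:
    def test_power_law_exponent_recovered(self):
        rng = np.random.default_rng(1)
        vals = mc.sample_power_law(5000, -2.0, 1.0, 1000.0, rng)
        fit = mc.fit_delta_K_power_law(vals)
        assert fit.ok
        assert fit.loglog_slope == pytest.approx(-2.0, rel=0.1)
        assert fit.loglog_r2 > 0.9

    def test_gaussian_data_fails_loglog_line(self):
        rng = np.random.default_rng(2)
        fit = mc.fit_size_gaussian(rng.normal(25.0, 4.0, 5000))
        assert fit.ok
        assert fit.loglog_r2 < 0.3
        assert fit.params["fit_r2"] > 0.9

    def test_constant_data_flagged_not_raised(self):
        fit = mc.fit_delta_K_power_law(np.full(100, 3.0))
        assert not fit.ok
        fit = mc.fit_size_gaussian(np.full(100, 3.0))
        assert not fit.ok


class TestFeatureSpaceCurve:
    def test_noiseless_inversion_exact(self):
        x = np.geomspace(0.4, 4.0, 60)
        res = mc.fit_feature_space_curve(1.2 * x**2, x)
        assert res["alpha"] == pytest.approx(1.2, abs=1e-6)
        assert res["beta"] == pytest.approx(2.0, abs=1e-6)

    def test_multiplicative_noise_recovers_exponent(self):
        rng = np.random.default_rng(3)
        x = np.geomspace(0.4, 4.0, 200)
        y = 1.2 * x**2 * np.exp(rng.normal(0, 0.2, x.size))
        res = mc.fit_feature_space_curve(y, x)
        assert res["beta"] == pytest.approx(2.0, rel=0.15)

    def test_single_cluster_flagged(self):
        res = mc.fit_feature_space_curve(np.full(50, 1.0), np.full(50, 1.0))
        assert not res["ok"]


class TestThresholdClassifier:
    def test_separated_groups_perfect_both_modes(self):
        y = np.array(["normal"] * 10 + ["success"] * 10 + ["failed"] * 10)
        X = np.concatenate([np.full(10, 1.0), np.full(10, 5.0), np.full(10, 9.0)])
        for mode in ("pooled_mean", "midpoint_of_means"):
            clf = mc.ThresholdClassifier(mode=mode).fit(X[:, None], y)
            assert brute_force_accuracy(clf, X[:, None], y) == 1.0

    def test_equal_means_threshold_and_chance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5.0, 1.0, 400)
        x -= x.mean() - 5.0  # force exact common mean
        y = np.array(["normal", "success"] * 200)
        clf = mc.ThresholdClassifier(order=("normal", "success")).fit(x[:, None], y)
        assert clf.signs_[0] * clf.thresholds_[0, 0] == pytest.approx(5.0, abs=1e-9)
        acc = brute_force_accuracy(clf, x[:, None], y)
        assert acc == pytest.approx(0.5, abs=0.1)

    def test_modes_differ_with_asymmetric_group_sizes(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 30)])
        y = np.array(["normal"] * 150 + ["success"] * 30)
        a = mc.ThresholdClassifier("pooled_mean", ("normal", "success")).fit(x[:, None], y)
        b = mc.ThresholdClassifier("midpoint_of_means", ("normal", "success")).fit(x[:, None], y)
        assert a.thresholds_[0, 0] != b.thresholds_[0, 0]
        for clf in (a, b):
            res_acc = brute_force_accuracy(clf, x[:, None], y)
            assert res_acc == np.mean(clf.predict(x[:, None]) == y)

    def test_modes_coincide_for_balanced_symmetric_groups(self):
        x = np.concatenate([np.linspace(-1, 1, 50), np.linspace(3, 5, 50)])
        y = np.array(["normal"] * 50 + ["success"] * 50)
        a = mc.ThresholdClassifier("pooled_mean", ("normal", "success")).fit(x[:, None], y)
        b = mc.ThresholdClassifier("midpoint_of_means", ("normal", "success")).fit(x[:, None], y)
        assert a.thresholds_[0, 0] == pytest.approx(b.thresholds_[0, 0], abs=1e-12)

    def test_empty_group_rejected(self):
        X = np.array([[1.0], [2.0]])
        y = np.array(["normal", "normal"])
        with pytest.raises(ValueError):
            mc.ThresholdClassifier().fit(X, y)

    def test_2d_grid_accuracy_matches_brute_force(self, norm_cohort):
        X = norm_cohort[["delta_K_tilde", "ell_tilde_inv"]].to_numpy()
        y = norm_cohort["group"].to_numpy()
        clf = mc.ThresholdClassifier("midpoint_of_means").fit(X, y)
        res = mc.threshold_classifier(
            norm_cohort, ["delta_K_tilde", "ell_tilde_inv"], mode="midpoint_of_means"
        )
        assert res.mean_accuracy == pytest.approx(brute_force_accuracy(clf, X, y))


class TestMultinomialLogistic:
    def test_seeded_runs_bitwise_identical(self, norm_cohort):
        r1 = mc.multinomial_logistic(
            norm_cohort, ["delta_K_tilde", "ell_tilde_inv"], n_permutations=30, seed=9
        )
        r2 = mc.multinomial_logistic(
            norm_cohort, ["delta_K_tilde", "ell_tilde_inv"], n_permutations=30, seed=9
        )
        assert np.array_equal(r1.accuracies, r2.accuracies)

    def test_two_features_beat_one(self, norm_cohort):
        one = mc.multinomial_logistic(
            norm_cohort, ["mean_curvedness"], n_permutations=150, seed=0
        )
        two = mc.multinomial_logistic(
            norm_cohort, ["delta_K_tilde", "ell_tilde_inv"], n_permutations=150, seed=0
        )
        assert two.mean_accuracy - one.mean_accuracy > 3 * two.sd_accuracy

    def test_too_small_groups_rejected(self):
        table = pd.DataFrame(
            {"group": ["normal", "success", "failed"], "delta_K": [1, 2, 3], "ell": [1, 2, 3]}
        )
        with pytest.raises(ValueError):
            mc.multinomial_logistic(table, ["delta_K"])


@pytest.fixture(scope="module")
def binary_data(norm_cohort):
    sub = norm_cohort[norm_cohort.group != "normal"]
    X = sub[["delta_K_tilde", "ell_tilde_inv"]].to_numpy()
    y = sub["group"].to_numpy()
    return X, y


class TestPenalizedSizeLogistic:
    def test_zero_penalty_matches_unpenalized_mle(self, binary_data):
        X, y = binary_data
        ours = mc.PenalizedSizeLogistic(lambda_=0.0).fit(X, y)
        ref = LogisticRegression(C=np.inf, max_iter=50000, tol=1e-14).fit(X, y)
        assert np.abs(ours.coef_ - ref.coef_[0]).max() < 1e-4
        assert abs(ours.intercept_ - ref.intercept_[0]) < 1e-4

    def test_large_penalty_kills_size_coefficient(self, binary_data):
        X, y = binary_data
        clf = mc.PenalizedSizeLogistic(lambda_=100.0, size_index=1).fit(X, y)
        assert clf.coef_[1] == 0.0
        assert clf.coef_[0] != 0.0  # pure-shape boundary

    def test_sweep_reports_band_and_smooth_accuracy(self, norm_cohort):
        res = mc.lasso_boundary_sweep(norm_cohort)
        assert len(res.accuracies) >= 15
        assert np.all(np.abs(np.diff(res.accuracies)) < 0.15)
        lo, hi = res.params["boundary_iqr_shape_axis"]
        assert np.isfinite(lo) and np.isfinite(hi) and hi >= lo

    def test_accuracy_equals_brute_force(self, binary_data):
        X, y = binary_data
        clf = mc.PenalizedSizeLogistic(lambda_=0.01).fit(X, y)
        assert np.mean(clf.predict(X) == y) == brute_force_accuracy(clf, X, y)

    def test_sklearn_protocol(self):
        clf = mc.PenalizedSizeLogistic(lambda_=0.5)
        params = clf.get_params()
        assert params["lambda_"] == 0.5
        clf.set_params(lambda_=0.1)
        assert clf.lambda_ == 0.1
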