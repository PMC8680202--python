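"""Clinical feature preprocessing, RFE, logistic fitting and the 12-test fixture."""

import json

import numpy as np
import pytest

from cfmhl.io import ClinicalTable
from cfmhl.models import (
    FeatureTable,
    SeverityModel,
    build_expanded_features,
    filter_tests_by_availability,
    fit_logistic,
    fit_random_forest,
    impute_and_standardize,
    predict,
    rfe_select,
    table1_fixture,
)
from cfmhl.screen import ScoreVector


def clinical(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"t{j}" for j in range(values.shape[1])]
    return ClinicalTable([f"s{i}" for i in range(values.shape[0])], names, values)


class TestAvailabilityFilter:
    def test_drops_above_threshold(self):
        vals = np.ones((10, 2))
        vals[:3, 0] = np.nan  # 30% missing
        table = filter_tests_by_availability(clinical(vals), 0.2)
        assert table.test_names == ["t1"]

    def test_keeps_fully_observed(self):
        table = filter_tests_by_availability(clinical(np.ones((5, 3))), 0.2)
        assert table.test_names == ["t0", "t1", "t2"]

    def test_boundary_kept_at_threshold(self):
        vals = np.ones((10, 1))
        vals[:3, 0] = np.nan
        assert filter_tests_by_availability(clinical(vals), 0.3).test_names == ["t0"]

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            filter_tests_by_availability(clinical(np.ones((2, 1))), 1.0)


class TestImputeStandardize:
    def test_median_imputation(self):
        vals = np.array([[1.0], [np.nan], [3.0]])
        _, record = impute_and_standardize(clinical(vals))
        assert record.medians[0] == 2.0

    def test_training_features_are_zscored(self):
        rng = np.random.default_rng(0)
        features, _ = impute_and_standardize(clinical(rng.normal(5, 3, (50, 4))))
        np.testing.assert_allclose(features.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(features.values.std(axis=0), 1, atol=1e-12)

    def test_record_applied_to_test_data_uses_training_statistics(self):
        train = clinical([[0.0], [2.0], [4.0]])  # mean 2, sd sqrt(8/3)
        test = clinical([[100.0], [np.nan]])
        _, record = impute_and_standardize(train)
        out = record.apply(test)
        sd = np.sqrt(8 / 3)
        assert out.values[0, 0] == pytest.approx((100 - 2) / sd)
        # missing test value imputed with the TRAINING median (2), not 100
        assert out.values[1, 0] == pytest.approx(0.0)

    def test_zero_variance_scaled_by_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            features, record = impute_and_standardize(clinical([[5.0], [5.0]]))
        assert record.scales[0] == 1.0
        np.testing.assert_array_equal(features.values, 0.0)

    def test_all_missing_test_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            impute_and_standardize(clinical([[np.nan], [np.nan]]))


class TestRfe:
    def _planted(self, n=200, seed=5):
        rng = np.random.default_rng(seed)
        y = rng.random(n) < 0.5
        X = rng.normal(size=(n, 5))
        X[:, 2] = y + rng.normal(scale=0.3, size=n)  # noisy copy of the label
        X = (X - X.mean(0)) / X.std(0)
        table = FeatureTable([f"s{i}" for i in range(n)], [f"f{j}" for j in range(5)], X)
        return table, y

    def test_planted_signal_survives_to_last(self):
        table, y = self._planted()
        kept, eliminated = rfe_select(table, y, n_keep=1)
        assert kept == ["f2"]
        assert len(eliminated) == 4

    def test_keep_all_is_identity(self):
        table, y = self._planted()
        kept, eliminated = rfe_select(table, y, n_keep=5)
        assert kept == table.feature_names
        assert eliminated == []

    def test_n_keep_zero_rejected(self):
        table, y = self._planted()
        with pytest.raises(ValueError):
            rfe_select(table, y, n_keep=0)

    def test_deterministic(self):
        table, y = self._planted()
        assert rfe_select(table, y, 2) == rfe_select(table, y, 2)

    def test_agrees_with_reference_eliminator(self):
        """Cross-check against scikit-learn's RFE with the same estimator."""
        from sklearn.feature_selection import RFE
        from sklearn.linear_model import LogisticRegression

        table, y = self._planted(seed=9)
        kept, _ = rfe_select(table, y, n_keep=2)
        ref = RFE(LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000), n_features_to_select=2, step=1)
        ref.fit(table.values, y.astype(int))
        ref_kept = [n for n, s in zip(table.feature_names, ref.support_) if s]
        assert sorted(kept) == sorted(ref_kept)


class TestFitLogistic:
    def test_uninformative_feature_has_near_zero_coefficient(self):
        rng = np.random.default_rng(1)
        n = 4000
        y = np.repeat([False, True], n // 2)
        X = np.zeros((n, 1))  # identical for both classes
        table = FeatureTable([f"s{i}" for i in range(n)], ["flat"], X)
        with pytest.warns(UserWarning):
            model = fit_logistic(table, y)  # zero-variance -> ridge path
        assert abs(model.coefficient("flat")) < 1e-6

    @pytest.mark.parametrize("n", [500, 5000])
    def test_recovers_generating_coefficients(self, n):
        rng = np.random.default_rng(12)
        beta = np.array([1.2, -0.8])
        intercept = 0.3
        X = rng.normal(size=(n, 2))
        p = 1 / (1 + np.exp(-(intercept + X @ beta)))
        y = rng.random(n) < p
        table = FeatureTable([f"s{i}" for i in range(n)], ["a", "b"], X)
        model = fit_logistic(table, y)
        # ML asymptotics: within 3 standard errors of the truth
        se = np.sqrt(4 / n)  # conservative bound for standardized features
        for est, true in zip(model.coefficients, beta):
            assert abs(est - true) < 3 * max(se, 0.15)

    def test_matches_statsmodels_reference(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        y = rng.random(300) < 1 / (1 + np.exp(-X[:, 0]))
        table = FeatureTable([f"s{i}" for i in range(300)], ["a", "b"], X)
        model = fit_logistic(table, y)
        ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(model.coefficients, ref.params[1:], atol=1e-6)
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-6)

    def test_separable_data_falls_back_to_ridge(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = X[:, 0] > 0
        table = FeatureTable([f"s{i}" for i in range(40)], ["x"], X)
        with pytest.warns(UserWarning, match="ridge"):
            model = fit_logistic(table, y)
        assert model.metadata["estimator"] == "logistic-ridge"
        assert np.isfinite(model.coefficients).all()

    def test_single_class_rejected(self):
        table = FeatureTable(["s0", "s1"], ["x"], np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            fit_logistic(table, [True, True])


class TestPredict:
    def test_zero_linear_predictor_gives_half(self):
        model = SeverityModel(["a", "b"], np.array([1.0, -2.0]), intercept=0.0)
        table = FeatureTable(["s0"], ["a", "b"], np.zeros((1, 2)))
        assert predict(model, table).iloc[0] == pytest.approx(0.5)

    def test_fixture_at_forced_zero_predictor(self):
        model = table1_fixture()
        table = FeatureTable(
            ["s0"], model.feature_names, np.zeros((1, len(model.feature_names)))
        )
        with pytest.warns(UserWarning, match="relative"):
            assert predict(model, table).iloc[0] == pytest.approx(0.5)

    def test_monotone_in_positive_coefficient_feature(self):
        model = SeverityModel(["a", "b"], np.array([0.9, -0.4]), intercept=-0.2)
        grid = np.linspace(-3, 3, 25)
        table = FeatureTable(
            [f"s{i}" for i in range(25)],
            ["a", "b"],
            np.column_stack([grid, np.zeros(25)]),
        )
        probs = predict(model, table).to_numpy()
        assert (np.diff(probs) > 0).all()
        assert ((probs > 0) & (probs < 1)).all()

    def test_standardization_applied_from_model(self):
        model = SeverityModel(
            ["a"], np.array([1.0]), intercept=0.0, standardization={"a": (10.0, 2.0)}
        )
        table = FeatureTable(["s0"], ["a"], np.array([[10.0]]))
        assert predict(model, table).iloc[0] == pytest.approx(0.5)

    def test_missing_feature_column_rejected(self):
        model = SeverityModel(["a"], np.array([1.0]), intercept=0.0)
        table = FeatureTable(["s0"], ["b"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="absent"):
            predict(model, table)


class TestExpandedFeatures:
    def test_adds_score_column(self):
        table = FeatureTable([f"s{i}" for i in range(10)], ["a"], np.zeros((10, 1)))
        scores = ScoreVector([f"s{i}" for i in range(10)], np.linspace(0, 1, 10))
        out = build_expanded_features(table, scores)
        assert out.feature_names == ["a", "umhl_sap_score"]
        assert out.provenance["umhl_sap_score"] == "methylation"
        np.testing.assert_allclose(out.values[:, 1], np.linspace(0, 1, 10))

    def test_one_sided_samples_dropped_with_warning(self):
        table = FeatureTable(["s0", "s1"], ["a"], np.zeros((2, 1)))
        scores = ScoreVector(["s1", "s2"], np.array([0.4, 0.6]))
        with pytest.warns(UserWarning, match="dropped"):
            out = build_expanded_features(table, scores)
        assert out.sample_ids == ["s1"]

    def test_disjoint_samples_rejected(self):
        table = FeatureTable(["s0"], ["a"], np.zeros((1, 1)))
        scores = ScoreVector(["zz"], np.array([0.4]))
        with pytest.raises(ValueError):
            build_expanded_features(table, scores)


class TestTable1Fixture:
    def test_twelve_features(self):
        model = table1_fixture()
        assert len(model.feature_names) == 12
        assert len(model.coefficients) == 12
        assert model.intercept is None

    @pytest.mark.parametrize(
        "test, coef",
        [
            ("Creatinine level", 0.2109),
            ("Absolute lymphocyte count", -1.4145),
            ("Red blood cell count", -3.8955),
            ("Urea nitrogen", 0.7063),
        ],
    )
    def test_printed_coefficients(self, test, coef):
        assert table1_fixture().coefficient(test) == coef

    def test_metadata_carries_units_and_ranges(self):
        model = table1_fixture()
        meta = model.metadata["tests"]["Creatinine level"]
        assert meta["unit"] == "µmol/L"
        assert meta["min"] < meta["mean"] < meta["max"]

    def test_round_trips_through_json_bit_exactly(self, tmp_path):
        model = table1_fixture()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SeverityModel.from_json(path)
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.intercept is None
        assert back.metadata == json.loads(json.dumps(model.metadata))


class TestRandomForest:
    def test_learns_planted_signal_deterministically(self):
        rng = np.random.default_rng(8)
        n = 200
        y = rng.random(n) < 0.5
        X = rng.normal(size=(n, 6))
        X[:, 0] += 2.0 * y
        table = FeatureTable([f"s{i}" for i in range(n)], [f"f{j}" for j in range(6)], X)
        clf1 = fit_random_forest(table, y, seed=1, n_trees=100)
        clf2 = fit_random_forest(table, y, seed=1, n_trees=100)
        p1 = clf1.predict_proba(table.values)[:, 1]
        np.testing.assert_array_equal(p1, clf2.predict_proba(table.values)[:, 1])
        assert ((p1 > 0.5) == y).mean() > 0.9
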