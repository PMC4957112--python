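"""End-to-end estimators: validation, determinism, scaling, persistence."""

import numpy as np
import pytest
from sklearn.base import clone

from rbforest import (
    FeatureScaler,
    ModelFormatError,
    RandomBitsForestClassifier,
    RandomBitsForestRegressor,
    load_model,
    save_model,
)

FAST = dict(n_chains=4, n_steps=5, n_candidates=16, n_trees=20, random_state=0)


@pytest.fixture(scope="module")
def clf_data():
    rng = np.random.default_rng(42)
    X = rng.standard_normal((120, 6))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    return X, y


@pytest.fixture(scope="module")
def fitted_clf(clf_data):
    X, y = clf_data
    return RandomBitsForestClassifier(**FAST).fit(X, y)


class TestScaler:
    def test_standardizes_to_zero_mean_unit_sd(self, rng):
        X = rng.normal(5.0, 3.0, size=(50, 4))
        sc = FeatureScaler.fit(X)
        Z = sc.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_feature_maps_to_zero(self, rng):
        X = np.column_stack([np.full(30, 7.0), rng.normal(size=30)])
        Z = FeatureScaler.fit(X).transform(X)
        np.testing.assert_array_equal(Z[:, 0], 0.0)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.normal(size=(40, 3))
        Z = FeatureScaler.fit(X).transform(X)
        Z2 = FeatureScaler.fit(Z).transform(Z)
        np.testing.assert_allclose(Z2, Z, atol=1e-12)

    def test_uses_sample_sd(self):
        X = np.array([[0.0], [2.0]])
        sc = FeatureScaler.fit(X)
        assert sc.sds[0] == pytest.approx(np.sqrt(2.0))  # ddof=1, not n


class TestFitValidation:
    def test_missing_values_rejected(self, clf_data):
        X, y = clf_data
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            RandomBitsForestClassifier(**FAST).fit(Xbad, y)

    def test_multiclass_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 3, 30)
        with pytest.raises(ValueError, match="binary"):
            RandomBitsForestClassifier(**FAST).fit(X, y)

    def test_predict_column_mismatch_rejected(self, fitted_clf, rng):
        with pytest.raises(ValueError, match="features"):
            fitted_clf.predict(rng.normal(size=(5, 9)))

    def test_sklearn_clone_compatible(self):
        est = RandomBitsForestClassifier(**FAST)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


class TestDeterminismAndInvariance:
    def test_refit_reproduces_predictions(self, clf_data):
        X, y = clf_data
        p1 = RandomBitsForestClassifier(**FAST).fit(X, y).predict_proba(X)[:, 1]
        p2 = RandomBitsForestClassifier(**FAST).fit(X, y).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(p1, p2)

    def test_batch_of_one_matches_batch_of_many(self, fitted_clf, rng):
        Xn = rng.normal(size=(10, 6))
        many = fitted_clf.predict_proba(Xn)[:, 1]
        singles = np.array([fitted_clf.predict_proba(Xn[i : i + 1])[0, 1] for i in range(10)])
        np.testing.assert_array_equal(many, singles)

    def test_affine_rescaling_of_inputs_is_absorbed(self, clf_data):
        # scaling a raw column in both train and test is removed by the
        # scaler, so with identical seeds the model is unchanged
        X, y = clf_data
        Xs = X.copy()
        Xs[:, 2] = 10.0 * Xs[:, 2] - 3.0
        p1 = RandomBitsForestClassifier(**FAST).fit(X, y).predict_proba(X)[:, 1]
        p2 = RandomBitsForestClassifier(**FAST).fit(Xs, y).predict_proba(Xs)[:, 1]
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestRegressor:
    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(40, 3))
        model = RandomBitsForestRegressor(**FAST).fit(X, np.full(40, 2.5))
        np.testing.assert_allclose(model.predict(rng.normal(size=(10, 3))), 2.5)

    def test_predictions_within_target_range(self, rng):
        X = rng.normal(size=(100, 4))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=100)
        model = RandomBitsForestRegressor(**FAST).fit(X, y)
        preds = model.predict(rng.normal(size=(50, 4)))
        assert preds.min() >= y.min() and preds.max() <= y.max()

    def test_learns_simple_signal(self, rng):
        X = rng.normal(size=(300, 3))
        y = X[:, 0]
        model = RandomBitsForestRegressor(
            n_chains=16, n_steps=10, n_candidates=64, n_trees=50, random_state=1
        ).fit(X[:200], y[:200])
        resid = model.predict(X[200:]) - y[200:]
        assert np.sqrt(np.mean(resid**2)) < 0.5  # well below sd(y) = 1


class TestClassifierOutput:
    def test_probabilities_valid(self, fitted_clf, clf_data):
        X, y = clf_data
        proba = fitted_clf.predict_proba(X)
        assert proba.shape == (len(X), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all() and (proba <= 1).all()

    def test_labels_are_original_classes(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.where(X[:, 0] > 0, "case", "control")
        model = RandomBitsForestClassifier(**FAST).fit(X, y)
        assert set(model.predict(X)) <= {"case", "control"}

    def test_separable_data_learned(self, fitted_clf, clf_data):
        X, y = clf_data
        assert (fitted_clf.predict(X) == y).mean() > 0.9


class TestPersistence:
    def test_round_trip_reproduces_predictions(self, fitted_clf, tmp_path, rng):
        path = tmp_path / "model.rbf"
        save_model(fitted_clf, path)
        loaded = load_model(path)
        Xn = rng.normal(size=(100, 6))
        np.testing.assert_array_equal(
            fitted_clf.predict_proba(Xn), loaded.predict_proba(Xn)
        )
        assert list(loaded.classes_) == list(fitted_clf.classes_)

    def test_serialization_is_deterministic(self, clf_data, tmp_path):
        X, y = clf_data
        paths = []
        for name in ("a.rbf", "b.rbf"):
            m = RandomBitsForestClassifier(**FAST).fit(X, y)
            p = tmp_path / name
            save_model(m, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_truncated_file_rejected(self, fitted_clf, tmp_path):
        path = tmp_path / "model.rbf"
        save_model(fitted_clf, path)
        path.write_bytes(path.read_bytes()[:-40])
        with pytest.raises(ModelFormatError, match="truncated"):
            load_model(path)

    def test_corrupted_payload_rejected(self, fitted_clf, tmp_path):
        path = tmp_path / "model.rbf"
        save_model(fitted_clf, path)
        blob = bytearray(path.read_bytes())
        blob[-10] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(ModelFormatError, match="checksum"):
            load_model(path)

    def test_wrong_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.rbf"
        path.write_bytes(b"this is not a model file")
        with pytest.raises(ModelFormatError, match="magic"):
            load_model(path)

    def test_unfitted_model_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="not fitted"):
            save_model(RandomBitsForestClassifier(**FAST), tmp_path / "x.rbf")
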