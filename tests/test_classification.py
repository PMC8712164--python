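import warnings

import numpy as np
import pytest

from osteotex.classification import (
    SCALAR_FEATURES,
    FeatureVector,
    extract_features,
    features_from_dataframe,
    features_to_dataframe,
    kfold_cv,
    predict,
    train_random_forest,
    train_svm,
)
from osteotex.image import RadiographImage
from osteotex.synthetic import PhantomSpec, generate_phantom


def toy_features(n_per_class=10, sep=6.0, seed=0, with_hog=False):
    """Two well-separated Gaussian clouds in the 8 scalar slots."""
    rng = np.random.default_rng(seed)
    out = []
    for label, center in ((+1, sep), (-1, -sep)):
        for _ in range(n_per_class):
            vals = rng.normal(center, 1.0, len(SCALAR_FEATURES))
            hog = rng.random(384) if with_hog else None
            out.append(FeatureVector(
                scalars=dict(zip(SCALAR_FEATURES, vals)), hog=hog, label=label
            ))
    return out


class TestFeatureVector:
    def test_scalar_order_enforced(self):
        bad = dict(zip(reversed(SCALAR_FEATURES), range(8)))
        with pytest.raises(ValueError, match="in order"):
            FeatureVector(scalars=bad)

    def test_array_lengths(self):
        fv = toy_features(1, with_hog=True)[0]
        assert fv.as_array(with_hog=True).shape == (392,)
        assert fv.as_array(with_hog=False).shape == (8,)

    def test_dataframe_roundtrip(self):
        feats = toy_features(3, with_hog=True)
        df = features_to_dataframe(feats)
        back = features_from_dataframe(df)
        for a, b in zip(feats, back):
            assert a.scalars == pytest.approx(b.scalars)
            np.testing.assert_allclose(a.hog, b.hog)
            assert a.label == b.label


class TestExtractFeatures:
    def test_constant_image_degenerate_contract(self):
        img = RadiographImage(np.full((32, 32), 128.0))
        fv = extract_features(img, with_hog=False)
        expected = {
            "entropy": 0.0, "energy": 1.0, "gini": 0.0, "skewness": 0.0,
            "contrast": 0.0, "correlation": 0.0, "homogeneity": 1.0,
            "entropy_product": 0.0,
        }
        assert fv.scalars == pytest.approx(expected)

    def test_deterministic_and_schema_stable(self):
        img = generate_phantom(PhantomSpec(label="cancerous", seed=11))
        a = extract_features(img, with_hog=True)
        b = extract_features(img, with_hog=True)
        assert tuple(a.scalars) == SCALAR_FEATURES
        assert a.scalars == b.scalars
        np.testing.assert_array_equal(a.hog, b.hog)
        assert a.label == +1

    def test_hog_flag_leaves_scalars_bit_identical(self):
        img = generate_phantom(PhantomSpec(label="healthy", seed=7))
        with_h = extract_features(img, with_hog=True)
        without = extract_features(img, with_hog=False)
        assert with_h.scalars == without.scalars  # exact equality
        assert without.hog is None and with_h.hog is not None


class TestSVM:
    def test_separable_clouds_perfect_training_accuracy(self):
        data = toy_features()
        clf = train_svm(data, with_hog=False)
        X = np.stack([f.as_array(with_hog=False) for f in data])
        y = np.array([f.label for f in data])
        np.testing.assert_array_equal(predict(clf, X), y)
        assert clf.support_vector_count >= 2

    def test_deterministic_across_refits(self):
        data = toy_features()
        a = train_svm(data, with_hog=False)
        b = train_svm(data, with_hog=False)
        np.testing.assert_array_equal(a.model.coef_, b.model.coef_)
        np.testing.assert_array_equal(a.model.intercept_, b.model.intercept_)

    def test_label_flip_negates_decision(self):
        data = toy_features()
        flipped = [FeatureVector(scalars=f.scalars, hog=f.hog, label=-f.label)
                   for f in data]
        X = np.stack([f.as_array(with_hog=False) for f in data])
        a = predict(train_svm(data, with_hog=False), X)
        b = predict(train_svm(flipped, with_hog=False), X)
        np.testing.assert_array_equal(a, -b)

    def test_single_class_rejected(self):
        data = [f for f in toy_features() if f.label == 1]
        with pytest.raises(ValueError, match="per class"):
            train_svm(data, with_hog=False)

    def test_scaler_learned_from_training_data_only(self):
        data = toy_features()
        clf = train_svm(data, with_hog=False)
        X = np.stack([f.as_array(with_hog=False) for f in data])
        np.testing.assert_allclose(clf.scaler.mean_, X.mean(axis=0))

    def test_prediction_invariant_to_affine_feature_rescaling(self):
        data = toy_features()
        scaled = [
            FeatureVector(
                scalars={k: 10.0 * v + 3.0 for k, v in f.scalars.items()},
                hog=f.hog, label=f.label,
            )
            for f in data
        ]
        Xa = np.stack([f.as_array(with_hog=False) for f in data])
        Xb = np.stack([f.as_array(with_hog=False) for f in scaled])
        pa = predict(train_svm(data, with_hog=False), Xa)
        pb = predict(train_svm(scaled, with_hog=False), Xb)
        np.testing.assert_array_equal(pa, pb)

    def test_sgd_solver_available(self):
        data = toy_features()
        clf = train_svm(data, with_hog=False, solver="sgd")
        X = np.stack([f.as_array(with_hog=False) for f in data])
        assert set(np.unique(predict(clf, X))) <= {1, -1}


class TestRandomForest:
    def test_separable_clouds_recovered(self):
        data = toy_features()
        clf = train_random_forest(data, with_hog=False, seed=1)
        X = np.stack([f.as_array(with_hog=False) for f in data])
        y = np.array([f.label for f in data])
        np.testing.assert_array_equal(predict(clf, X), y)

    def test_seeded_determinism(self):
        data = toy_features(sep=1.0)
        X = np.stack([f.as_array(with_hog=False) for f in data])
        a = predict(train_random_forest(data, with_hog=False, seed=5), X)
        b = predict(train_random_forest(data, with_hog=False, seed=5), X)
        np.testing.assert_array_equal(a, b)

    def test_exact_vote_tie_goes_to_cancerous(self):
        data = toy_features()
        clf = train_random_forest(data, with_hog=False, seed=0)
        proba = np.array([[0.5, 0.5]])
        pos = list(clf.model.classes_).index(1)
        assert np.where(proba[:, pos] >= 0.5, 1, -1)[0] == 1


class TestPredictValidation:
    def test_dimension_mismatch_names_lengths(self):
        clf = train_svm(toy_features(), with_hog=False)
        with pytest.raises(ValueError, match="expects 8, got 5"):
            predict(clf, np.zeros((1, 5)))


class TestKFoldCV:
    def test_every_example_predicted_exactly_once(self):
        data = toy_features(n_per_class=12)
        res = kfold_cv(data, k=5, model_kind="svm")
        assert res.confusion.total == len(data)
        assert len(res.fold_accuracies) == 5
        assert set(np.unique(res.y_pred)) <= {1, -1}

    def test_perfect_separation_gives_full_accuracy(self):
        res = kfold_cv(toy_features(n_per_class=15), k=5, model_kind="svm")
        assert res.pooled_accuracy == 100.0
        assert res.confusion.fn == res.confusion.fp == 0

    def test_class_smaller_than_k_rejected(self):
        data = toy_features(n_per_class=3)
        with pytest.raises(ValueError, match="at least k"):
            kfold_cv(data, k=5)

    def test_seed_changes_split_not_contract(self):
        data = toy_features(n_per_class=10, sep=0.5, seed=3)
        r1 = kfold_cv(data, k=5, seed=1)
        r2 = kfold_cv(data, k=5, seed=1)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)
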