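"""Normalization, stratified splitting, SVM training and evaluation."""

import numpy as np
import pytest

from neuroload.classifier import (
    FeatureMatrix,
    build_feature_matrix,
    classify_features,
    evaluate,
    normalize,
    split,
    train_svm,
)
from neuroload.errors import PreconditionError


def fmatrix(X, labels, names=None):
    names = names or [f"f{i}" for i in range(np.asarray(X).shape[1])]
    return FeatureMatrix(X=np.asarray(X, float),
                         labels=np.array(labels, dtype=object),
                         feature_names=names)


def gaussian_clusters(rng, n_per=100, sep=6.0, sigma=0.5):
    a = rng.normal([0, 0], sigma, (n_per, 2))
    b = rng.normal([sep, sep], sigma, (n_per, 2))
    X = np.vstack([a, b])
    y = ["low"] * n_per + ["high"] * n_per
    return fmatrix(X, y)


class TestNormalize:
    def test_fit_column_maps_to_unit_interval(self):
        fm = fmatrix([[2.0], [4.0], [6.0]], ["low", "high", "low"])
        out = normalize(fm, np.arange(3))
        np.testing.assert_allclose(out.X[:, 0], [0, 0.5, 1])

    def test_test_rows_extrapolate_unclipped(self):
        fm = fmatrix([[2.0], [6.0], [8.0]], ["low", "high", "low"])
        out = normalize(fm, np.array([0, 1]))   # fit extrema (2, 6)
        assert out.X[2, 0] == pytest.approx(1.5)

    def test_constant_feature_dropped_with_warning(self, caplog):
        fm = fmatrix([[1.0, 3.0], [1.0, 5.0], [1.0, 9.0]], ["low", "high", "low"])
        import logging

        with caplog.at_level(logging.WARNING):
            out = normalize(fm, np.arange(3))
        assert out.feature_names == ["f1"]
        assert "constant" in caplog.text


class TestSplit:
    def test_paper_sized_pool_split(self, rng):
        X = rng.standard_normal((3000, 2))
        y = ["high"] * 1500 + ["low"] * 1500
        fm = fmatrix(X, y)
        train, test = split(fm, n_train=2700, seed=0)
        assert len(train) == 2700 and len(test) == 300
        test_labels = fm.labels[test].astype(str)
        assert (test_labels == "high").sum() == 150
        assert (test_labels == "low").sum() == 150

    def test_singleton_test_set(self, rng):
        fm = gaussian_clusters(rng, n_per=5)
        train, test = split(fm, n_train=9, stratify=False, seed=1)
        assert len(test) == 1

    def test_deterministic_per_seed(self, rng):
        fm = gaussian_clusters(rng)
        a = split(fm, 150, seed=3)
        b = split(fm, 150, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_class_too_small_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        fm = fmatrix(X, ["high"] * 9 + ["low"])
        with pytest.raises(PreconditionError):
            split(fm, n_train=9, seed=0)


class TestSVM:
    def test_separable_clusters_linear_kernel(self, rng):
        fm = gaussian_clusters(rng)
        model = train_svm(fm, kernel="linear")
        rep = evaluate(model, fm, np.arange(fm.n_rows), np.arange(fm.n_rows))
        assert rep.train_accuracy_pct == 100.0

    def test_xor_needs_rbf(self, rng):
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]], float)
        X = np.vstack([rng.normal(c, 0.3, (50, 2)) for c in centers])
        y = ["low"] * 100 + ["high"] * 100
        fm = fmatrix(X, y)
        rows = np.arange(fm.n_rows)
        rbf = evaluate(train_svm(fm, kernel="rbf"), fm, rows, rows)
        lin = evaluate(train_svm(fm, kernel="linear"), fm, rows, rows)
        assert rbf.train_accuracy_pct == 100.0
        assert lin.train_accuracy_pct <= 80.0

    def test_contradictory_duplicates_no_crash(self):
        fm = fmatrix([[0.0, 0.0]] * 4 + [[1.0, 1.0]] * 2,
                     ["low", "low", "high", "high", "low", "high"])
        rows = np.arange(fm.n_rows)
        rep = evaluate(train_svm(fm), fm, rows, rows)
        assert rep.train_accuracy_pct < 100.0

    def test_single_class_rejected(self, rng):
        fm = fmatrix(rng.standard_normal((10, 2)), ["low"] * 10)
        with pytest.raises(PreconditionError):
            train_svm(fm)

    def test_decision_depends_only_on_support_vectors(self, rng):
        fm = gaussian_clusters(rng, n_per=40)
        model = train_svm(fm, kernel="linear")
        sv = np.sort(model.support_)
        grid = rng.standard_normal((50, 2)) * 4
        pred_full = model.predict(grid)
        reduced = fmatrix(fm.X[sv], fm.labels[sv])
        model2 = train_svm(reduced, kernel="linear")
        np.testing.assert_array_equal(model2.predict(grid), pred_full)

    def test_permuted_labels_near_chance(self, rng):
        accs = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            fm = gaussian_clusters(g, n_per=100)
            labels = fm.labels.copy()
            g.shuffle(labels)
            fm_perm = fmatrix(fm.X, labels)
            rep = classify_features(fm_perm, n_train=150, seed=seed)
            accs.append(rep.test_accuracy_pct)
        assert np.mean(accs) == pytest.approx(50.0, abs=10.0)


class TestPipelineInvariances:
    def test_prescaling_does_not_change_predictions(self, rng):
        fm = gaussian_clusters(rng)
        scaled = fmatrix(fm.X * np.array([100.0, 0.01]) + 5.0, fm.labels)
        r1 = classify_features(fm, n_train=150, seed=2)
        r2 = classify_features(scaled, n_train=150, seed=2)
        assert r1.test_accuracy_pct == r2.test_accuracy_pct
        assert r1.confusion == r2.confusion

    def test_train_accuracy_beats_test_on_average(self, rng):
        diffs = []
        for seed in range(10):
            g = np.random.default_rng(100 + seed)
            fm = gaussian_clusters(g, sep=1.5, sigma=1.0)
            rep = classify_features(fm, n_train=150, seed=seed)
            diffs.append(rep.train_accuracy_pct - rep.test_accuracy_pct)
        assert np.mean(diffs) >= 0.0


class TestBuildFeatureMatrix:
    def test_default_columns_and_labels(self, band_summary, entropy_result):
        fm = build_feature_matrix(band_summary, entropy_result)
        assert fm.feature_names == ["beta_ratio_T7", "beta_ratio_T8",
                                    "shannon", "sampen"]
        assert set(fm.labels) == {"high", "low"}
        assert not np.isnan(fm.X).any()

    def test_unpooled_turns_drop_right(self, band_summary, entropy_result):
        pooled = build_feature_matrix(band_summary, entropy_result)
        unpooled = build_feature_matrix(band_summary, entropy_result,
                                        pool_turns=False)
        assert unpooled.n_rows < pooled.n_rows

    def test_entropy_feature_without_table_rejected(self, band_summary):
        with pytest.raises(PreconditionError):
            build_feature_matrix(band_summary, None, features=("shannon",))
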