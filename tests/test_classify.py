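"""Cross-validation, confusion-matrix metrics, and the noise harness."""

import numpy as np
import pytest

from pfb.classify import (CLASSIFIER_FAMILIES, ClassifierSpec, ConfusionMatrix,
                          class_average_difference, cross_validate, cv_accuracy,
                          kfold_split, metrics, noise_sweep)
from pfb.errors import ParameterError
from pfb.phantom import generate_dataset

# Published benchmark operating points for the six classifier families:
# (TH, FH, TU, FU) confusion counts with their reported accuracy and F1 (%).
REFERENCE_OPERATING_POINTS = {
    "svm-linear": ((167, 24, 75, 18), 85.21, 83.48),
    "svm-rbf": ((172, 18, 81, 13), 89.08, 87.84),
    "svm-gaussian": ((173, 24, 75, 12), 87.32, 85.61),
    "svm-poly": ((161, 11, 88, 24), 87.68, 86.80),
    "dtree": ((168, 24, 75, 17), 85.56, 83.83),
    "logreg": ((158, 24, 75, 27), 82.04, 80.37),
}


def separable_table(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 2)) + np.where(y[:, None] == 1, 6.0, 0.0)
    return X, y


class TestKfoldSplit:
    def test_cohort_sized_partition(self):
        """284 subjects into 10 folds: sizes 28 or 29, summing to 284."""
        labels = np.array([0] * 185 + [1] * 99)
        folds = kfold_split(284, 10, labels, rng_seed=0)
        sizes = np.bincount(folds)
        assert sorted(set(sizes)) == [28, 29]
        assert sizes.sum() == 284

    def test_disjoint_cover(self):
        labels = np.array([0, 1] * 30)
        folds = kfold_split(60, 10, labels, rng_seed=1)
        assert len(folds) == 60
        assert set(folds) == set(range(10))

    def test_same_seed_same_folds(self):
        labels = np.array([0, 1] * 25)
        a = kfold_split(50, 10, labels, rng_seed=4)
        b = kfold_split(50, 10, labels, rng_seed=4)
        assert np.array_equal(a, b)

    def test_small_class_falls_back_with_warning(self):
        labels = np.array([0] * 47 + [1] * 3)
        with pytest.warns(UserWarning, match="fewer than"):
            folds = kfold_split(50, 10, labels, rng_seed=0)
        assert set(folds) == set(range(10))


class TestCrossValidate:
    @pytest.mark.parametrize("family", CLASSIFIER_FAMILIES)
    def test_separable_data_is_perfect(self, family):
        X, y = separable_table()
        cm = cross_validate(ClassifierSpec(family), X, y, k=5, rng_seed=0)
        assert metrics(cm)["accuracy"] == 100.0
        assert cm.total == len(y)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(8)
        X, y = separable_table(n=200, seed=8)
        y_perm = rng.permutation(y)
        acc = cv_accuracy(ClassifierSpec("svm-rbf"), X, y_perm, rng_seed=2)
        assert 0.4 <= acc <= 0.6

    def test_deterministic(self):
        X, y = separable_table(n=40, seed=3)
        a = cross_validate(ClassifierSpec("dtree", rng_seed=1), X, y, k=5,
                           rng_seed=9, augment=True)
        b = cross_validate(ClassifierSpec("dtree", rng_seed=1), X, y, k=5,
                           rng_seed=9, augment=True)
        assert a == b

    def test_augment_balances_training_only(self):
        # imbalanced table: pooled matrix still covers every subject once
        rng = np.random.default_rng(5)
        y = np.array([0] * 80 + [1] * 30)
        X = rng.standard_normal((110, 3)) + y[:, None]
        cm = cross_validate(ClassifierSpec("logreg"), X, y, k=10, augment=True,
                            rng_seed=0)
        assert cm.total == 110
        assert cm.TH + cm.FU == 80
        assert cm.TU + cm.FH == 30


class TestMetrics:
    @pytest.mark.parametrize("family", sorted(REFERENCE_OPERATING_POINTS))
    def test_reproduces_reference_rows(self, family):
        """Accuracy and macro-F1 match the published operating points to 2 dp."""
        (TH, FH, TU, FU), acc, f1 = REFERENCE_OPERATING_POINTS[family]
        m = metrics(ConfusionMatrix(TH, FH, TU, FU))
        assert m["accuracy"] == acc
        assert m["f1"] == f1

    def test_reference_totals_match_cohort(self):
        for (TH, FH, TU, FU), _, _ in REFERENCE_OPERATING_POINTS.values():
            assert TH + FH + TU + FU == 284

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(TH=185, FH=0, TU=99, FU=0))
        assert m == {"accuracy": 100.0, "f1": 100.0}

    def test_degenerate_class_f1_zero(self):
        # everything predicted healthy: unhealthy-view F1 collapses to 0
        m = metrics(ConfusionMatrix(TH=50, FH=50, TU=0, FU=0))
        assert m["f1"] == pytest.approx(100 * (2 / 3) / 2, abs=0.01)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestPhantomClassification:
    def test_high_separation_is_learnable(self):
        from pfb.features import extract_features

        ds = generate_dataset(12, separation=1.0, seed=21, size=128)
        X = np.array([extract_features(im, mk).values
                      for im, mk in zip(ds.images, ds.masks)])
        acc = cv_accuracy(ClassifierSpec("svm-rbf"), X, ds.labels(), k=6,
                          rng_seed=0)
        assert acc >= 0.9

    def test_noise_sweep_shape_and_vanishing_noise(self):
        ds = generate_dataset(10, separation=1.0, seed=31, size=128)
        res = noise_sweep(ClassifierSpec("svm-rbf"), ds, [60.0, 20.0],
                          rng_seed=1, k=5)
        assert set(res) == {"clean", "60", "20"}
        assert abs(res["60"] - res["clean"]) <= 2.0


class TestClassAverageDifference:
    def test_identical_distributions_much_flatter_than_separated(self):
        """At separation 0 the class averages agree up to sampling noise;
        real class structure raises the mean absolute difference severalfold."""
        d0 = class_average_difference(
            generate_dataset(20, separation=0.0, seed=2, size=96), frame=64)
        d1 = class_average_difference(
            generate_dataset(20, separation=1.0, seed=2, size=96), frame=64)
        assert np.abs(d0).mean() < 10.0
        assert np.abs(d0).mean() < 0.33 * np.abs(d1).mean()

    def test_single_image_per_class_is_plain_difference(self):
        ds = generate_dataset(1, separation=1.0, seed=3, size=96)
        diff = class_average_difference(ds, frame=64)
        assert diff.shape == (64, 64)

    def test_class_geometry_shows_up_at_the_neck_boundary(self):
        """With class-dependent neck width, the strongest differences sit
        near the bone boundary rather than deep inside or far outside."""
        ds = generate_dataset(10, separation=1.0, seed=4, size=128)
        diff = class_average_difference(ds, frame=96)
        hot = np.abs(diff) > 0.5 * np.abs(diff).max()
        # hot pixels concentrated in the central body of the frame
        rows, cols = np.nonzero(hot)
        assert rows.size > 0
        assert 10 <= rows.mean() <= 86 and 10 <= cols.mean() <= 86
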