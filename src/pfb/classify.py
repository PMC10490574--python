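"""Classifier training and evaluation under stratified 10-fold CV.

Six classifier families are supported: SVMs with linear, polynomial, RBF and
Gaussian kernels, a Gini decision tree, and L2 logistic regression. "RBF"
and "Gaussian" use the same kernel form with two different kernel-scale
policies: the RBF variant uses the 1/(d * var) scale heuristic, the
Gaussian variant a bandwidth from the median pairwise distance of the
training rows.

Results are pooled over folds into a single confusion matrix whose cells
follow the healthy/unhealthy naming: TH (true healthy), FH (false healthy =
predicted healthy but truly unhealthy), TU (true unhealthy), FU (false
unhealthy = predicted unhealthy but truly healthy). Accuracy and
macro-averaged F1 are reported in percent, rounded to 2 decimals.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError, StratificationError
from .features import standardize_fit_apply
from .image import HEALTHY, UNHEALTHY

CLASSIFIER_FAMILIES = ("svm-linear", "svm-poly", "svm-rbf", "svm-gaussian",
                       "dtree", "logreg")


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameters: tuple = ()  # (key, value) pairs; hashable for caching
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ParameterError(
                f"unknown classifier family {self.family!r}; "
                f"choose from {CLASSIFIER_FAMILIES}")

    def params(self) -> dict:
        return dict(self.hyperparameters)


def _median_distance_gamma(X: np.ndarray) -> float:
    n = len(X)
    if n > 200:  # subsample for the median heuristic
        rng = np.random.default_rng(0)
        X = X[rng.choice(n, 200, replace=False)]
    d = pdist(X)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med ** 2)


def build_classifier(spec: ClassifierSpec, X_train: np.ndarray):
    """Instantiate the scikit-learn estimator for a spec (unfitted)."""
    p = spec.params()
    C = float(p.get("C", 1.0))
    if spec.family == "svm-linear":
        return SVC(kernel="linear", C=C)
    if spec.family == "svm-poly":
        return SVC(kernel="poly", degree=int(p.get("degree", 3)), C=C, gamma="scale")
    if spec.family == "svm-rbf":
        return SVC(kernel="rbf", C=C, gamma="scale")
    if spec.family == "svm-gaussian":
        return SVC(kernel="rbf", C=C, gamma=_median_distance_gamma(X_train))
    if spec.family == "dtree":
        return DecisionTreeClassifier(criterion="gini",
                                      max_depth=p.get("max_depth"),
                                      random_state=spec.rng_seed)
    if spec.family == "logreg":
        # L2 penalty (the sklearn default) at strength C
        return LogisticRegression(C=C, max_iter=int(p.get("max_iter", 2000)))
    raise ParameterError(spec.family)


@dataclasses.dataclass
class ConfusionMatrix:
    """Pooled healthy/unhealthy confusion counts."""

    TH: int
    FH: int
    TU: int
    FU: int

    def __post_init__(self) -> None:
        if min(self.TH, self.FH, self.TU, self.FU) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TH + self.FH + self.TU + self.FU

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TH=int(np.sum((y_pred == HEALTHY) & (y_true == HEALTHY))),
            FH=int(np.sum((y_pred == HEALTHY) & (y_true == UNHEALTHY))),
            TU=int(np.sum((y_pred == UNHEALTHY) & (y_true == UNHEALTHY))),
            FU=int(np.sum((y_pred == UNHEALTHY) & (y_true == HEALTHY))),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.TH + other.TH, self.FH + other.FH,
                               self.TU + other.TU, self.FU + other.FU)


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 2 * tp / denom


def metrics(cm: ConfusionMatrix) -> Dict[str, float]:
    """Accuracy and macro-F1 in percent, rounded to 2 decimals.

    Macro-F1 averages the F1 of the healthy-as-positive view (TP=TH, FP=FH,
    FN=FU) and the unhealthy-as-positive view (TP=TU, FP=FU, FN=FH).
    """
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    accuracy = 100.0 * (cm.TH + cm.TU) / cm.total
    f1_healthy = _f1(cm.TH, cm.FH, cm.FU)
    f1_unhealthy = _f1(cm.TU, cm.FU, cm.FH)
    macro_f1 = 100.0 * (f1_healthy + f1_unhealthy) / 2.0
    return {"accuracy": round(accuracy, 2), "f1": round(macro_f1, 2)}


def kfold_split(n: int, k: int = 10, labels: Optional[Sequence[int]] = None,
                rng_seed: int = 0) -> np.ndarray:
    """Fold assignment array (values 0..k-1), stratified when possible.

    If a class has fewer than k members, stratification is impossible; a
    plain shuffled partition is used with a warning.
    """
    if n < k:
        raise ParameterError(f"cannot split {n} subjects into {k} folds")
    assignment = np.empty(n, dtype=int)
    if labels is not None:
        labels = np.asarray(labels)
        counts = np.bincount(labels, minlength=2)
        if counts.min() == 0:
            raise StratificationError("both classes must be present")
        if counts.min() < k:
            warnings.warn(f"a class has fewer than {k} members; "
                          "falling back to an unstratified partition",
                          stacklevel=2)
            splitter = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
            for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n))):
                assignment[test_idx] = fold
            return assignment
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
            assignment[test_idx] = fold
        return assignment
    splitter = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n))):
        assignment[test_idx] = fold
    return assignment


def _oversample_minority(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Balance classes by resampling minority rows with replacement."""
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X, y
    minority = int(np.argmin(counts))
    deficit = int(abs(counts[0] - counts[1]))
    idx = np.nonzero(y == minority)[0]
    extra = rng.choice(idx, size=deficit, replace=True)
    return np.vstack([X, X[extra]]), np.concatenate([y, y[extra]])


def cross_validate(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, *,
                   k: int = 10, augment: bool = False, rng_seed: int = 0,
                   folds: Optional[np.ndarray] = None) -> ConfusionMatrix:
    """Pooled k-fold confusion matrix for one classifier.

    Per fold: optional minority-class balancing on the training rows only,
    standardization fitted on the training rows, classifier fit, test-fold
    predictions accumulated. Every subject is predicted exactly once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds is None:
        folds = kfold_split(len(y), k=k, labels=y, rng_seed=rng_seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    rng = np.random.default_rng(rng_seed)
    for fold in range(int(folds.max()) + 1):
        test = folds == fold
        X_tr, y_tr = X[~test], y[~test]
        if augment:
            X_tr, y_tr = _oversample_minority(X_tr, y_tr, rng)
        X_tr_z, X_te_z = standardize_fit_apply(X_tr, X[test])
        clf = build_classifier(spec, X_tr_z)
        clf.fit(X_tr_z, y_tr)
        pooled = pooled + ConfusionMatrix.from_predictions(y[test], clf.predict(X_te_z))
    return pooled


def cv_accuracy(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, *,
                k: int = 10, rng_seed: int = 0,
                folds: Optional[np.ndarray] = None) -> float:
    """Pooled CV accuracy as a fraction in [0, 1]."""
    cm = cross_validate(spec, X, y, k=k, rng_seed=rng_seed, folds=folds)
    return (cm.TH + cm.TU) / cm.total


def noise_sweep(spec: ClassifierSpec, dataset, snr_list_db: Sequence[float], *,
                rng_seed: int = 0, k: int = 10) -> Dict[str, float]:
    """CV accuracy after injecting Gaussian noise into test images.

    For each SNR, the test-fold images are degraded before feature
    extraction while training stays on clean-image features; the clean
    accuracy is reported under the key ``"clean"``. The dataset must carry
    ground-truth masks (features are recomputed per noisy image).
    """
    from .features import extract_features
    from .phantom import add_gaussian_noise

    if dataset.masks is None or any(m is None for m in dataset.masks):
        raise ParameterError("noise sweep needs a mask for every image")
    y = dataset.labels().astype(int)
    clean = np.array([extract_features(im, mk).values
                      for im, mk in zip(dataset.images, dataset.masks)])
    folds = kfold_split(len(y), k=k, labels=y, rng_seed=rng_seed)

    results: Dict[str, float] = {}
    variants = {"clean": clean}
    for snr in snr_list_db:
        noisy = np.array([
            extract_features(add_gaussian_noise(im, snr, rng_seed + 7919 * i), mk).values
            for i, (im, mk) in enumerate(zip(dataset.images, dataset.masks))])
        variants[f"{snr:g}"] = noisy

    for key, test_matrix in variants.items():
        correct = 0
        for fold in range(int(folds.max()) + 1):
            test = folds == fold
            X_tr_z, X_te_z = standardize_fit_apply(clean[~test], test_matrix[test])
            clf = build_classifier(spec, X_tr_z)
            clf.fit(X_tr_z, y[~test])
            correct += int((clf.predict(X_te_z) == y[test]).sum())
        results[key] = 100.0 * correct / len(y)
    return results


def class_average_difference(dataset, *, frame: int = 128) -> np.ndarray:
    """Mean canonical unhealthy image minus mean canonical healthy image.

    Each image is canonicalized (mirrored/cropped with its mask), resampled
    to a common ``frame`` x ``frame`` grid, and averaged per class.
    """
    from skimage.transform import resize

    from .geometry import crop_like

    if dataset.masks is None or any(m is None for m in dataset.masks):
        raise ParameterError("class averages need a mask for every image")
    sums = {HEALTHY: None, UNHEALTHY: None}
    counts = {HEALTHY: 0, UNHEALTHY: 0}
    for im, mk in zip(dataset.images, dataset.masks):
        crop = crop_like(mk, im.pixels, im.side)
        common = resize(crop, (frame, frame), order=1, anti_aliasing=True)
        lab = im.label
        sums[lab] = common if sums[lab] is None else sums[lab] + common
        counts[lab] += 1
    if counts[HEALTHY] == 0 or counts[UNHEALTHY] == 0:
        raise ParameterError("need at least one image per class")
    return sums[UNHEALTHY] / counts[UNHEALTHY] - sums[HEALTHY] / counts[HEALTHY]
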