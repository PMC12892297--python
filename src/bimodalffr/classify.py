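"""Objective discrimination of vowel FFR spectra with a linear SVM.

Features are 250-bin FFR amplitude spectra reduced to the top five
principal components; a one-against-one linear SVM (N(N-1)/2 = 3 binary
classifiers for the three vowels) is cross-validated subject-wise with a
3-fold split iterated many times.  A label-shuffled null distribution and
the empirical probability p = (a+1)/(n+1) provide significance, where a
counts null accuracies surpassing the median of the reference
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureSet",
    "ClassifierRun",
    "SignificanceResult",
    "pca_reduce",
    "ovo_svm",
    "cv_iterate",
    "null_run",
    "empirical_p",
]


@dataclass(frozen=True)
class FeatureSet:
    """Spectra (observations × bins) with vowel labels and subject grouping."""

    spectra: np.ndarray
    labels: np.ndarray  # vowel per observation
    subjects: np.ndarray  # subject per observation

    def __post_init__(self):
        n = self.spectra.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects length mismatch")


@dataclass(frozen=True)
class ClassifierRun:
    accuracies: np.ndarray  # one per iteration
    confusion: np.ndarray  # 3×3, row-normalized to percent
    classes: np.ndarray
    seed: int

    def __post_init__(self):
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass(frozen=True)
class SignificanceResult:
    a: int
    n: int
    p: float


def pca_reduce(
    train: np.ndarray, test: np.ndarray, k: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Fit a k-component PCA on the training spectra only; project both sets.

    Returns (train features, test features, loadings (k × bins), fraction of
    training variance explained).
    """
    if k > min(train.shape[1], train.shape[0] - 1):
        raise ValueError("k too large for the training set")
    if np.allclose(np.var(train, axis=0), 0):
        raise ValueError("degenerate (constant) training data")
    pca = PCA(n_components=k)
    ftr = pca.fit_transform(train)
    fte = pca.transform(test)
    return ftr, fte, pca.components_, float(pca.explained_variance_ratio_.sum())


def ovo_svm(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    c: float = 1.0,
) -> tuple[np.ndarray, int]:
    """One-against-one linear SVM prediction.

    Builds N(N-1)/2 binary max-margin classifiers and combines them by
    majority vote, ties broken by aggregate decision margin.  Returns
    (predicted labels, number of binary classifiers).
    """
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=c, decision_function_shape="ovo")
    clf.fit(train_x, train_y)
    n_binary = len(classes) * (len(classes) - 1) // 2
    return clf.predict(test_x), n_binary


def _iterate(
    features: FeatureSet,
    n_iter: int,
    n_folds: int,
    seed: int,
    k: int,
    shuffle_labels: bool,
    standardize: bool = True,
) -> ClassifierRun:
    subjects = np.unique(features.subjects)
    if len(subjects) % n_folds != 0:
        raise ValueError(
            f"{len(subjects)} subjects not divisible into {n_folds} folds; "
            "use a cohort size that is a multiple of the fold count"
        )
    classes = np.unique(features.labels)
    class_index = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    confusion = np.zeros((len(classes), len(classes)))
    per_fold = len(subjects) // n_folds
    for it in range(n_iter):
        labels = features.labels
        if shuffle_labels:
            labels = rng.permutation(labels)
        order = rng.permutation(subjects)
        folds = [set(order[i * per_fold : (i + 1) * per_fold]) for i in range(n_folds)]
        fold_accs = []
        for held in folds:
            te = np.isin(features.subjects, list(held))
            tr = ~te
            # group-integrity audit: a held-out subject never appears in training
            assert not (set(features.subjects[tr]) & set(features.subjects[te]))
            xtr, xte = features.spectra[tr], features.spectra[te]
            if standardize:
                scaler = StandardScaler().fit(xtr)
                xtr, xte = scaler.transform(xtr), scaler.transform(xte)
            ftr, fte, _, _ = pca_reduce(xtr, xte, k=min(k, xtr.shape[0] - 1))
            pred, _ = ovo_svm(ftr, labels[tr], fte)
            truth = labels[te]
            fold_accs.append(float(np.mean(pred == truth)))
            for t, p in zip(truth, pred):
                confusion[class_index[t], class_index[p]] += 1
        accs[it] = float(np.mean(fold_accs))
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = 100.0 * confusion / np.where(row_sums == 0, 1, row_sums)
    return ClassifierRun(accs, confusion, classes, seed)


def cv_iterate(
    features: FeatureSet,
    n_iter: int = 1000,
    n_folds: int = 3,
    seed: int = 0,
    k: int = 5,
) -> ClassifierRun:
    """Subject-wise 3-fold cross-validation iterated ``n_iter`` times.

    Each iteration shuffles subjects into equal folds, holds each fold out
    once (PCA and standardization fit on the training folds only), and
    records the mean held-out accuracy.  The grand confusion matrix
    accumulates all held-out predictions, row-normalized to percent.
    """
    return _iterate(features, n_iter, n_folds, seed, k, shuffle_labels=False)


def null_run(
    features: FeatureSet,
    n_iter: int = 1000,
    n_folds: int = 3,
    seed: int = 0,
    k: int = 5,
) -> ClassifierRun:
    """Label-shuffled null: labels are permuted across observations anew on
    each iteration before folding; otherwise identical to :func:`cv_iterate`."""
    return _iterate(features, n_iter, n_folds, seed, k, shuffle_labels=True)


def empirical_p(reference: np.ndarray, null: np.ndarray) -> SignificanceResult:
    """p = (a+1)/(n+1) with a = #{null values > median(reference)}.

    Also used for condition-vs-condition comparisons by passing one
    condition's accuracy distribution as the null.
    """
    reference = np.asarray(reference, dtype=float)
    null = np.asarray(null, dtype=float)
    if reference.size == 0 or null.size == 0:
        raise ValueError("empty distribution")
    a = int(np.sum(null > np.median(reference)))
    n = int(null.size)
    return SignificanceResult(a, n, (a + 1) / (n + 1))
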