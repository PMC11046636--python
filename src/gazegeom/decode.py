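"""Single-trial decoding of concepts from pre-onset gaze coordinates.

A linear discriminant (pooled within-class covariance, equal priors, small
ridge for numerical stability) is trained in a leave-one-trial-out scheme:
each trial in turn is held out, the majority class in the remaining trials
is randomly downsampled to the minority size (balancing the folds), and the
held-out trial is classified.  Significance is assessed by recomputing the
whole procedure under label permutations; the p value is the fraction of
permuted accuracies at least as large as the observed one.

Numbers are decoded as small (1-6) vs large (7-12) from the horizontal
coordinate alone; colors are decoded pairwise from both coordinates,
yielding a 12 x 12 accuracy matrix whose lower-triangle mean is the overall
accuracy and whose relation to conceptual distance is tested by
:func:`accuracy_vs_distance`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conceptspace import DissimilarityMatrix
from .errors import (ConfigurationError, DataError, DegenerateDataError,
                     UndefinedCorrelationError)

__all__ = [
    "DecodingResult",
    "AccuracyMatrix",
    "lda_train_predict",
    "loocv_balanced_accuracy",
    "permutation_pvalue",
    "pairwise_color_decoding",
    "accuracy_vs_distance",
    "small_large_labels",
]

_RIDGE_EPS = 1e-6


@dataclass
class DecodingResult:
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_perm: float
    n_trials: int
    seed: int

    def to_dict(self) -> dict:
        return {"observed_accuracy": self.observed_accuracy,
                "p_perm": self.p_perm,
                "n_perm": int(len(self.permuted_accuracies)),
                "n_trials": self.n_trials, "seed": self.seed}


@dataclass
class AccuracyMatrix:
    """Pairwise decoding accuracies; diagonal is undefined (NaN)."""

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        self.labels = tuple(str(w) for w in self.labels)
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise DataError("matrix shape does not match labels")
        self.matrix = m

    @property
    def overall(self) -> float:
        """Mean of the defined lower-triangle entries."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        vals = self.matrix[i, j]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise DataError("no defined pairwise accuracies")
        return float(vals.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))


def small_large_labels(words) -> np.ndarray:
    """Binary coding of number words: 'small' for 1-6, 'large' for 7-12."""
    vals = np.asarray([int(str(w)) for w in words])
    return np.where(vals <= 6, "small", "large")


def _class_stats(x: np.ndarray, mask: np.ndarray) -> tuple:
    sub = x[mask]
    mu = sub.mean(axis=0)
    dev = sub - mu
    return mu, dev.T @ dev, len(sub)


def lda_train_predict(train_features: np.ndarray, train_labels: np.ndarray,
                      test_feature: np.ndarray):
    """Classify one test point with a two-class pooled-covariance LDA.

    Equal priors; pooled within-class covariance regularized with
    ``eps * trace / d`` on the diagonal (eps = 1e-6); ties break toward the
    lexicographically smaller label.
    """
    x = np.atleast_2d(np.asarray(train_features, dtype=float))
    if x.shape[1] not in (1, 2):
        raise DataError("features must be 1- or 2-dimensional")
    y = np.asarray([str(v) for v in np.asarray(train_labels).ravel()])
    classes = sorted(set(y))
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes in training data, got {classes}")
    d = x.shape[1]
    mu0, s0, n0 = _class_stats(x, y == classes[0])
    mu1, s1, n1 = _class_stats(x, y == classes[1])
    pooled = (s0 + s1) / max(n0 + n1 - 2, 1)
    pooled = pooled + (_RIDGE_EPS * np.trace(pooled) / d + 1e-300) * np.eye(d)
    inv = np.linalg.inv(pooled)
    z = np.asarray(test_feature, dtype=float).reshape(d)
    d0 = (z - mu0) @ inv @ (z - mu0)
    d1 = (z - mu1) @ inv @ (z - mu1)
    # equal priors: smaller Mahalanobis distance wins; tie -> smaller label
    return classes[0] if d0 <= d1 else classes[1]


def _loocv(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
           upsample: bool) -> float:
    """Core leave-one-trial-out loop with per-fold class balancing."""
    n, d = x.shape
    classes = sorted(set(y.tolist()))
    codes = np.asarray([classes.index(v) for v in y])
    idx_by_class = [np.flatnonzero(codes == k) for k in (0, 1)]
    correct = 0
    eye = np.eye(d)
    for i in range(n):
        tr = [idx[idx != i] for idx in idx_by_class]
        n0, n1 = len(tr[0]), len(tr[1])
        if upsample:
            m = max(n0, n1)
            tr = [idx if len(idx) == m else rng.choice(idx, size=m, replace=True)
                  for idx in tr]
        else:
            m = min(n0, n1)
            tr = [idx if len(idx) == m else rng.choice(idx, size=m, replace=False)
                  for idx in tr]
        a, b = x[tr[0]], x[tr[1]]
        mu0, mu1 = a.mean(axis=0), b.mean(axis=0)
        da, db = a - mu0, b - mu1
        pooled = (da.T @ da + db.T @ db) / max(2 * len(tr[0]) - 2, 1)
        pooled = pooled + (_RIDGE_EPS * np.trace(pooled) / d + 1e-300) * eye
        inv = np.linalg.inv(pooled)
        z = x[i]
        d0 = (z - mu0) @ inv @ (z - mu0)
        d1 = (z - mu1) @ inv @ (z - mu1)
        pred = 0 if d0 <= d1 else 1
        correct += int(pred == codes[i])
    return correct / n


def _prepare(features, labels) -> tuple:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[1] not in (1, 2):
        raise DataError("features must be 1- or 2-dimensional")
    y = np.asarray([str(v) for v in np.asarray(labels).ravel()])
    if len(y) != len(x):
        raise DataError("features and labels have unequal lengths")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise DegenerateDataError(
            "each class needs at least 2 trials for leave-one-out balancing")
    return x, y


def loocv_balanced_accuracy(features, labels, seed: int = 0,
                            upsample: bool = False) -> float:
    """Leave-one-trial-out balanced LDA accuracy.

    One fold per trial; in each fold the majority class in the training set
    is downsampled without replacement (seeded) to the minority size (or,
    with ``upsample``, the minority is resampled up with replacement).
    """
    x, y = _prepare(features, labels)
    rng = np.random.default_rng(seed)
    return _loocv(x, y, rng, upsample)


def permutation_pvalue(features, labels, n_perm: int = 1000, seed: int = 0,
                       upsample: bool = False,
                       add_one: bool = False) -> DecodingResult:
    """Observed LOOCV accuracy against a label-permutation null.

    Each permutation shuffles the labels and reruns the full balanced LOOCV
    (fresh resampling per fold).  p = count(permuted >= observed) / n_perm;
    with ``add_one`` the (count+1)/(n_perm+1) estimator is used instead so p
    can never be exactly zero.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    x, y = _prepare(features, labels)
    rng = np.random.default_rng(seed)
    observed = _loocv(x, y, rng, upsample)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        permuted[k] = _loocv(x, rng.permutation(y), rng, upsample)
    count = int(np.sum(permuted >= observed))
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return DecodingResult(observed_accuracy=float(observed),
                          permuted_accuracies=permuted, p_perm=float(p),
                          n_trials=len(y), seed=seed)


def pairwise_color_decoding(trials: pd.DataFrame, seed: int = 0,
                            labels=None) -> AccuracyMatrix:
    """All-pairs balanced LOOCV LDA on (x, y) gaze features.

    For every unordered pair of concepts with at least 2 valid trials each,
    the pair's trials are decoded with 2D features; pairs failing the
    precondition stay NaN with a warning.  The matrix is explicitly
    symmetrized, and ``overall`` averages the lower triangle.
    """
    import warnings
    v = trials[trials["valid"]]
    if labels is None:
        labels = sorted(v["word"].astype(str).unique())
    labels = [str(w) for w in labels]
    n = len(labels)
    acc = np.full((n, n), np.nan)
    rng = np.random.default_rng(seed)
    feats = {w: v.loc[v["word"].astype(str) == w,
                      ["median_x_px", "median_y_px"]].to_numpy(float)
             for w in labels}
    any_defined = False
    for i in range(n):
        for j in range(i + 1, n):
            a, b = feats[labels[i]], feats[labels[j]]
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"pair ({labels[i]}, {labels[j]}) has too few "
                              "trials; accuracy undefined")
                continue
            x = np.vstack([a, b])
            y = np.array([labels[i]] * len(a) + [labels[j]] * len(b))
            acc[i, j] = acc[j, i] = _loocv(x, y, rng, upsample=False)
            any_defined = True
    if not any_defined:
        raise DataError("no pair had enough trials; empty result")
    acc = (acc + acc.T) / 2
    return AccuracyMatrix(tuple(labels), acc)


def accuracy_vs_distance(acc: AccuracyMatrix, dm: DissimilarityMatrix) -> tuple:
    """Does decodability grow with conceptual distance?

    Spearman rho and OLS slope of lower-triangle accuracy on lower-triangle
    conceptual distance (NaN pairs excluded).
    """
    if acc.labels != dm.labels:
        raise DataError("accuracy and distance matrices must share labels")
    i, j = np.tril_indices(len(acc.labels), k=-1)
    a = acc.matrix[i, j]
    d = dm.matrix[i, j]
    keep = ~np.isnan(a)
    a, d = a[keep], d[keep]
    if len(a) < 4:
        raise DataError("need at least 4 defined pairs")
    if np.ptp(a) == 0:
        raise UndefinedCorrelationError("constant accuracies")
    from .trialstats import spearman_rho
    rho = spearman_rho(d, a)
    design = np.column_stack([d, np.ones_like(d)])
    (slope, _), *_ = np.linalg.lstsq(design, a, rcond=None)
    return float(rho), float(slope)
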