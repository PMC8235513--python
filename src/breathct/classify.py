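"""PCA+LDA breath classifier and the AUC-based evaluation metrics.

The study's classifier is two-class linear discriminant analysis on a PCA
score space: PCA reduces the 18 sensor features to ``n_components`` principal
components, then an LDA direction is computed from the pooled within-class
covariance (with a tiny ridge) and the decision threshold sits at the
midpoint of the projected class means (equal priors, matching the balanced
training design). Performance is reported as AUC with a standard error over
repeated random balanced splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import feature_values

POSITIVE_CLASS = "meal"


class PCALDAClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant analysis on a PCA score space.

    Parameters
    ----------
    n_components : number of principal components retained before LDA.
    positive_class : label treated as positive ("meal" here); if absent from
        the training labels, the lexicographically larger class is used.
    ridge : diagonal regularization added to the pooled covariance.

    Attributes
    ----------
    pca_ : fitted sklearn PCA (orthonormal loadings, centering included).
    direction_ : LDA discriminant direction in score space.
    threshold_ : decision threshold on the projected score.
    classes_ : the two class labels, ``[negative, positive]``.
    """

    def __init__(self, n_components: int = 13, positive_class=POSITIVE_CLASS, ridge: float = 1e-8):
        self.n_components = n_components
        self.positive_class = positive_class
        self.ridge = ridge

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        n, k = X.shape
        if self.n_components > min(n - 2, k):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-2, k)={min(n - 2, k)}"
            )
        if self.positive_class in classes:
            pos = self.positive_class
        else:
            pos = classes[-1]
        neg = classes[classes != pos][0]
        self.classes_ = np.array([neg, pos])

        self.pca_ = PCA(n_components=self.n_components).fit(X)
        T = self.pca_.transform(X)
        Tp, Tn = T[y == pos], T[y == neg]
        mu_p, mu_n = Tp.mean(axis=0), Tn.mean(axis=0)
        n_p, n_n = len(Tp), len(Tn)
        Sw = (np.cov(Tp, rowvar=False) * (n_p - 1) + np.cov(Tn, rowvar=False) * (n_n - 1))
        Sw = np.atleast_2d(Sw) / (n_p + n_n - 2)
        Sw = Sw + self.ridge * np.eye(self.n_components)
        self.direction_ = solve(Sw, mu_p - mu_n, assume_a="pos")
        self.threshold_ = float(0.5 * (mu_p + mu_n) @ self.direction_)
        self.n_features_in_ = k
        return self

    def decision_function(self, X):
        """Signed LDA score; positive values favor the positive class."""
        check_is_fitted(self, "direction_")
        X = check_array(X, dtype=float)
        return self.pca_.transform(X) @ self.direction_ - self.threshold_

    def predict(self, X):
        s = self.decision_function(X)
        return np.where(s >= 0, self.classes_[1], self.classes_[0])


def compute_auc(scores, labels, positive_class=POSITIVE_CLASS) -> float:
    """AUC as the pairwise probability that a positive outscores a negative.

    Equal scores receive 0.5 credit; this is the Mann-Whitney estimator and
    equals the trapezoidal area under the ROC curve.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive_class
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(pos.astype(int), scores))


@dataclass
class MetricSet:
    """Evaluation metrics of one scored test set (positive class = meal)."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    se: float = float("nan")  # standard error, filled when aggregating reps


def compute_metrics(scores, labels, threshold: float = 0.0, positive_class=POSITIVE_CLASS) -> MetricSet:
    """Confusion-matrix metrics of thresholded scores plus the AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    auc = compute_auc(scores, labels, positive_class)
    pred_pos = scores >= threshold
    is_pos = labels == positive_class
    tp = int(np.sum(pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    return MetricSet(
        auc=auc,
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


def balanced_split(
    data: pd.DataFrame,
    train_per_class: int,
    rng: np.random.Generator,
    positive_class=POSITIVE_CLASS,
) -> tuple[np.ndarray, np.ndarray]:
    """Random class-balanced train/rest row-position split of a feature table."""
    y = data["class"].to_numpy()
    train_idx = []
    for cls in np.unique(y):
        pos = np.flatnonzero(y == cls)
        if len(pos) < train_per_class:
            raise ValueError(
                f"class {cls!r} has {len(pos)} rows; need {train_per_class} for training"
            )
        train_idx.append(rng.choice(pos, size=train_per_class, replace=False))
    train = np.sort(np.concatenate(train_idx))
    rest = np.setdiff1d(np.arange(len(data)), train)
    return train, rest


def select_n_pcs(
    master: pd.DataFrame,
    grid,
    reps: int = 20,
    train_size: int = 48,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the PCA dimension by repeated random balanced subsampling.

    For each candidate dimension, ``reps`` random splits draw a balanced
    training set of ``train_size`` (half per class) and validate on the
    remaining samples; the dimension with the highest mean validation AUC
    wins (ties toward the smaller dimension). Returns the winner and a table
    of per-value mean AUC and its standard error.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)  # same splits are reused for every grid value
    rows = []
    X = feature_values(master)
    y = master["class"].to_numpy()
    for n_pcs in grid:
        aucs = []
        for rng in [np.random.default_rng(s) for s in rep_seeds]:
            train, val = balanced_split(master, train_size // 2, rng)
            clf = PCALDAClassifier(n_components=n_pcs).fit(X[train], y[train])
            aucs.append(compute_auc(clf.decision_function(X[val]), y[val]))
        aucs = np.asarray(aucs)
        rows.append(
            {
                "n_pcs": n_pcs,
                "auc_mean": aucs.mean(),
                "auc_se": aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table.sort_values(["auc_mean", "n_pcs"], ascending=[False, True]).iloc[0]["n_pcs"])
    return best, table
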