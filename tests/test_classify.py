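"""PCA+LDA classifier, AUC estimator and dimensionality selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import solve

from breathct import (
    PCALDAClassifier,
    compute_auc,
    compute_metrics,
    select_n_pcs,
)
from breathct.preprocess import FEATURE_COLUMNS


def pair_count_auc(scores, labels, positive="meal"):
    """Brute-force pairwise estimator with 0.5 tie credit."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def blobs(rng, n=40, k=6, sep=6.0):
    X = rng.normal(size=(n, k))
    y = np.array(["meal" if i < n // 2 else "no-meal" for i in range(n)])
    X[y == "meal"] += sep / np.sqrt(k)
    return X, y


class TestPCALDAClassifier:
    def test_separated_blobs_reach_perfect_training_auc(self, rng):
        X, y = blobs(rng)
        clf = PCALDAClassifier(n_components=2).fit(X, y)
        assert compute_auc(clf.decision_function(X), y) == 1.0

    def test_shuffled_labels_give_chance_auc(self, rng):
        X, y = blobs(rng, n=60, sep=0.0)
        aucs = []
        for _ in range(20):
            ys = rng.permutation(y)
            clf = PCALDAClassifier(n_components=2).fit(X, ys)
            aucs.append(compute_auc(clf.decision_function(X), ys))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_full_pca_matches_direct_lda_oracle(self, rng):
        """PCA with all components is a rotation: scores equal plain LDA."""
        X, y = blobs(rng, n=50, k=5, sep=2.0)
        clf = PCALDAClassifier(n_components=5, ridge=0.0).fit(X, y)
        # direct pooled-covariance LDA in the original space
        Xp, Xn = X[y == "meal"], X[y == "no-meal"]
        Sw = (np.cov(Xp, rowvar=False) * (len(Xp) - 1) + np.cov(Xn, rowvar=False) * (len(Xn) - 1))
        Sw /= len(X) - 2
        w = solve(Sw, Xp.mean(0) - Xn.mean(0), assume_a="pos")
        s_direct = X @ w - 0.5 * (Xp.mean(0) + Xn.mean(0)) @ w
        s_ours = clf.decision_function(X)
        np.testing.assert_allclose(s_ours, s_direct, atol=1e-8)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        with pytest.raises(ValueError, match="class"):
            PCALDAClassifier(n_components=2).fit(X, np.repeat("meal", 20))

    def test_dimension_bound_enforced(self, rng):
        X, y = blobs(rng, n=10, k=6)
        with pytest.raises(ValueError, match="n_components"):
            PCALDAClassifier(n_components=9).fit(X, y)

    def test_predict_agrees_with_decision_sign(self, rng):
        X, y = blobs(rng, sep=2.0)
        clf = PCALDAClassifier(n_components=3).fit(X, y)
        pred = clf.predict(X)
        s = clf.decision_function(X)
        assert ((pred == "meal") == (s >= 0)).all()


class TestAUC:
    def test_perfect_separation_and_ties(self):
        labels = np.array(["meal", "meal", "no-meal", "no-meal"])
        assert compute_auc([5, 4, 2, 1], labels) == 1.0
        assert compute_auc([1, 1, 1, 1], labels) == 0.5

    def test_worked_pair_fixture(self):
        scores = [0.8, 0.4, 0.6, 0.2]
        labels = ["meal", "meal", "no-meal", "no-meal"]
        assert compute_auc(scores, labels) == 0.75

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10**6), st.integers(2, 50))
    def test_equals_brute_force_pair_counting(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.array(["meal", "no-meal"] + list(rng.choice(["meal", "no-meal"], n - 2)))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # coarse grid forces ties
        assert compute_auc(scores, labels) == pytest.approx(pair_count_auc(scores, labels))

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.choice(["meal", "no-meal"], 30)
        labels[:2] = ["meal", "no-meal"]
        scores = rng.normal(size=30)
        a = compute_auc(scores, labels)
        assert compute_auc(np.exp(3 * scores), labels) == pytest.approx(a)

    def test_label_inversion_complements_auc(self, rng):
        labels = np.array(["meal"] * 10 + ["no-meal"] * 12)
        scores = rng.normal(size=22)
        a = compute_auc(scores, labels)
        flipped = np.where(labels == "meal", "no-meal", "meal")
        assert compute_auc(scores, flipped) == pytest.approx(1 - a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([1, 2], ["meal", "meal"])


class TestMetrics:
    def test_all_correct(self):
        labels = np.array(["meal", "no-meal"])
        m = compute_metrics([1.0, -1.0], labels)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        labels = np.array(["meal", "no-meal", "no-meal"])
        m = compute_metrics([1.0, 2.0, 3.0], labels)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_confusion_fixture(self):
        # TP=3 FP=1 FN=1 TN=5
        labels = np.array(["meal"] * 4 + ["no-meal"] * 6)
        scores = np.array([1, 1, 1, -1, 1, -1, -1, -1, -1, -1], dtype=float)
        m = compute_metrics(scores, labels)
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(5 / 6)


def _master_frame(rng, n_per_class=60, k=18, n_nuisance=3):
    """High-variance nuisance in the leading PCs; class shift in later ones.

    A PCA truncation below ``n_nuisance + 1`` components cannot see the class
    signal, so dimensionality selection must go past the nuisance block.
    """
    n = 2 * n_per_class
    y = np.array(["meal"] * n_per_class + ["no-meal"] * n_per_class)
    X = rng.normal(size=(n, k)) * 0.3
    X[:, :n_nuisance] += 2.0 * rng.normal(size=(n, n_nuisance))
    X[:, n_nuisance] += np.where(y == "meal", 0.5, 0.0)
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df.insert(0, "sample_id", [f"r{i}" for i in range(n)])
    df["class"] = y
    return df


class TestSelectNPCs:
    def test_single_element_grid_returned(self, rng):
        df = _master_frame(rng)
        best, table = select_n_pcs(df, [7], reps=3, seed=0)
        assert best == 7 and len(table) == 1

    def test_prefers_dimension_that_spans_the_signal(self, rng):
        df = _master_frame(rng, n_nuisance=3)
        best, table = select_n_pcs(df, [2, 6], reps=10, seed=0)
        assert best == 6

    def test_reports_standard_error_over_repetitions(self, rng):
        df = _master_frame(rng)
        _, table = select_n_pcs(df, [4], reps=10, seed=0)
        assert (table["auc_se"] > 0).all()

    def test_insufficient_class_counts_rejected(self, rng):
        df = _master_frame(rng, n_per_class=10)
        with pytest.raises(ValueError, match="training"):
            select_n_pcs(df, [3], reps=2, train_size=48, seed=0)
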