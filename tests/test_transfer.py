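"""The five transfer estimators against closed forms and matrix oracles."""

import numpy as np
import pytest

from breathct import (
    CORAL,
    DirectStandardization,
    PiecewiseDirectStandardization,
    PLSDACalibrationTransfer,
    PLSDAComponentRemoval,
    coral_lambda,
)
from breathct import pls_fit


@pytest.fixture()
def affine_pair(rng):
    """Row-aligned blocks linked by an exact invertible affine map."""
    k = 18
    Xm = 2.0 + rng.normal(size=(40, k))
    G = np.eye(k) + 0.3 * rng.normal(size=(k, k))
    b = rng.normal(size=k)
    Xs = Xm @ G + b
    return Xm, Xs, G, b


class TestDirectStandardization:
    def test_identity_link_gives_identity_matrix(self, rng):
        Xm = rng.normal(size=(40, 18))
        t = DirectStandardization().fit(Xm, Xm)
        np.testing.assert_allclose(t.B_, np.eye(18), atol=1e-8)

    def test_scalar_gain_inverts(self, rng):
        Xm = rng.normal(size=(40, 18))
        t = DirectStandardization().fit(2 * Xm, Xm)
        np.testing.assert_allclose(t.B_, 0.5 * np.eye(18), atol=1e-8)

    def test_recovers_inverse_of_affine_link(self, affine_pair):
        Xm, Xs, G, b = affine_pair
        t = DirectStandardization().fit(Xs, Xm)
        np.testing.assert_allclose(t.B_, np.linalg.inv(G), atol=1e-6)
        np.testing.assert_allclose(t.transform(Xs), Xm, atol=1e-6)

    def test_transform_is_affine_matrix_product(self, affine_pair, rng):
        Xm, Xs, _, _ = affine_pair
        t = DirectStandardization().fit(Xs, Xm)
        Z = rng.normal(size=(7, 18))
        np.testing.assert_allclose(t.transform(Z), Z @ t.B_ + t.intercept_, atol=1e-12)

    def test_input_validation(self, rng):
        Xm = rng.normal(size=(40, 18))
        with pytest.raises(ValueError, match="identical"):
            DirectStandardization().fit(np.ones((10, 18)), Xm[:10])
        t = DirectStandardization().fit(Xm, Xm)
        with pytest.raises(ValueError, match="columns"):
            t.transform(rng.normal(size=(5, 4)))


class TestPiecewiseDirectStandardization:
    def test_window_one_inverts_diagonal_gain(self, rng):
        k = 18
        Xm = 2.0 + rng.normal(size=(30, k))
        g = rng.uniform(0.5, 2.0, size=k)
        Xs = Xm * g
        t = PiecewiseDirectStandardization(window=1).fit(Xs, Xm)
        np.testing.assert_allclose(np.diag(t.B_), 1.0 / g, atol=1e-8)
        off = t.B_ - np.diag(np.diag(t.B_))
        assert np.abs(off).max() == 0.0

    def test_identity_link_window_one(self, rng):
        Xm = rng.normal(size=(30, 18))
        t = PiecewiseDirectStandardization(window=1).fit(Xm, Xm)
        np.testing.assert_allclose(t.B_, np.eye(18), atol=1e-8)
        np.testing.assert_allclose(t.intercept_, 0.0, atol=1e-8)

    def test_full_window_full_rank_equals_ds(self, affine_pair):
        Xm, Xs, _, _ = affine_pair
        pds = PiecewiseDirectStandardization(window=18, n_components=None).fit(Xs, Xm)
        ds = DirectStandardization().fit(Xs, Xm)
        np.testing.assert_allclose(pds.transform(Xs), ds.transform(Xs), atol=1e-6)

    def test_band_structure_outside_window_is_zero(self, rng):
        Xm = rng.normal(size=(40, 18))
        Xs = Xm + 0.1 * rng.normal(size=(40, 18))
        t = PiecewiseDirectStandardization(window=5).fit(Xs, Xm)
        for j in range(18):
            outside = np.ones(18, dtype=bool)
            outside[max(0, j - 2): j + 3] = False
            assert np.abs(t.B_[outside, j]).max() == 0.0

    def test_banded_transform_matches_dense_product(self, rng):
        Xm = rng.normal(size=(40, 18))
        Xs = Xm + 0.1 * rng.normal(size=(40, 18))
        t = PiecewiseDirectStandardization(window=7).fit(Xs, Xm)
        Z = rng.normal(size=(9, 18))
        np.testing.assert_allclose(t.transform(Z), Z @ t.B_ + t.intercept_, atol=1e-12)

    def test_even_window_rejected(self, rng):
        X = rng.normal(size=(20, 18))
        with pytest.raises(ValueError, match="odd"):
            PiecewiseDirectStandardization(window=4).fit(X, X)


class TestPLSDAComponentRemoval:
    def _offset_blocks(self, rng, n=30, k=10):
        Xm = rng.normal(size=(n, k))
        v = rng.normal(size=k)
        v *= 2.0 / np.linalg.norm(v)
        return Xm, Xm + v, v

    def test_single_component_removes_mean_offset_direction(self, rng):
        Xm, Xs, v = self._offset_blocks(rng)
        rem = PLSDAComponentRemoval.from_blocks(Xm, Xs)
        gap = rem.transform(Xm).mean(axis=0) - rem.transform(Xs).mean(axis=0)
        assert abs(gap @ (v / np.linalg.norm(v))) < 1e-6

    def test_removal_is_idempotent(self, rng):
        Xm, Xs, _ = self._offset_blocks(rng)
        rem = PLSDAComponentRemoval.from_blocks(Xm, Xs, n_components=2)
        once = rem.transform(Xm)
        twice = rem.transform(once)
        assert np.linalg.norm(twice - once) < 1e-8

    def test_membership_no_longer_predictable_after_removal(self, rng):
        """Held-out rows of the offset scenario: membership AUC drops to chance."""
        from breathct.classify import compute_auc

        Xm, Xs, _ = self._offset_blocks(rng, n=60)
        fit_m, hold_m = Xm[:40], Xm[40:]
        fit_s, hold_s = Xs[:40], Xs[40:]
        rem = PLSDAComponentRemoval.from_blocks(fit_m, fit_s)
        X = np.vstack([rem.transform(fit_m), rem.transform(fit_s)])
        y = np.array(["m"] * 40 + ["s"] * 40)
        member = pls_fit(X, np.where(y == "m", 1.0, -1.0), 1)
        scores = member.predict(np.vstack([rem.transform(hold_m), rem.transform(hold_s)]))[:, 0]
        labels = np.array(["m"] * 20 + ["s"] * 20)
        assert compute_auc(scores, labels, positive_class="m") <= 0.6

    def test_component_count_validation(self, rng):
        Xm, Xs, _ = self._offset_blocks(rng)
        with pytest.raises(ValueError, match=">= 1"):
            PLSDAComponentRemoval(n_components=0).fit(
                np.vstack([Xm, Xs]), np.array([0] * 30 + [1] * 30)
            )


class TestPLSDACalibrationTransfer:
    def _master(self, rng, n=60, k=12):
        X = rng.normal(size=(n, k))
        y = np.where(rng.random(n) < 0.5, "meal", "no-meal")
        X[y == "meal"] += 0.8
        return X, y

    def test_identical_transfer_blocks_give_identity_map(self, rng):
        X, y = self._master(rng)
        ct = X[:20]
        t = PLSDACalibrationTransfer(n_components=3).fit(X, y, Xm_ct=ct, Xs_ct=ct)
        np.testing.assert_allclose(t.M_, np.eye(3), atol=1e-8)

    def test_scalar_case_is_ratio_of_inner_products(self, rng):
        X, y = self._master(rng)
        Xs_ct = X[:20] + 0.2 * rng.normal(size=(20, 12))
        t = PLSDACalibrationTransfer(n_components=1).fit(X, y, Xm_ct=X[:20], Xs_ct=Xs_ct)
        tm = t.project_master(X[:20])[:, 0]
        ts = t.project_master(Xs_ct)[:, 0]
        assert t.M_[0, 0] == pytest.approx((ts @ tm) / (ts @ ts), abs=1e-10)

    def test_matches_step_by_step_matrix_oracle(self, rng):
        X, y = self._master(rng)
        G = np.eye(12) + 0.2 * rng.normal(size=(12, 12))
        Xm_ct, Xs_ct = X[:24], X[:24] @ G
        c = 3
        t = PLSDACalibrationTransfer(n_components=c).fit(X, y, Xm_ct=Xm_ct, Xs_ct=Xs_ct)
        model = pls_fit(X, np.where(y == "no-meal", 1.0, -1.0), c)
        R = model.W @ np.linalg.inv(model.P.T @ model.W)
        Tm = (Xm_ct - model.x_mean) @ R
        Ts = (Xs_ct - model.x_mean) @ R
        M = np.linalg.inv(Ts.T @ Ts) @ Ts.T @ Tm
        np.testing.assert_allclose(np.abs(t.M_), np.abs(M), atol=1e-8)
        Z = rng.normal(size=(5, 12))
        np.testing.assert_allclose(t.transform(Z), (Z - model.x_mean) @ R @ M, atol=1e-8)

    def test_master_projection_reproduces_pls_scores(self, rng):
        X, y = self._master(rng)
        t = PLSDACalibrationTransfer(n_components=2).fit(X, y, Xm_ct=X[:20], Xs_ct=X[:20])
        np.testing.assert_allclose(t.project_master(X), t.pls_.scores(X), atol=1e-12)

    def test_singular_score_gram_suggests_smaller_c(self, rng):
        X, y = self._master(rng)
        Xs_ct = np.tile(X[:1], (10, 1))  # rank-1 transfer block
        with pytest.raises(ValueError, match="n_components"):
            PLSDACalibrationTransfer(n_components=3).fit(X, y, Xm_ct=X[:10], Xs_ct=Xs_ct)


class TestCORAL:
    def test_equal_blocks_give_identity(self, rng):
        X = rng.normal(size=(50, 18))
        t = CORAL(lam=0.1).fit(X, X)
        np.testing.assert_allclose(t.A_, np.eye(18), atol=1e-8)
        np.testing.assert_allclose(t.transform(X), X, atol=1e-7)

    def test_scalar_closed_form(self, rng):
        xm = rng.normal(size=(30, 1))
        xs = 3.0 * rng.normal(size=(40, 1))
        lam = 0.5
        t = CORAL(lam=lam).fit(xm, xs)
        expected = np.sqrt((np.sum(xs**2) + lam) / (np.sum(xm**2) + lam))
        assert t.A_[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_second_moment_matching_identity(self, rng):
        Xm = rng.normal(size=(60, 18))
        Xs = rng.normal(size=(60, 18)) @ (np.eye(18) + 0.4 * rng.normal(size=(18, 18)))
        lam = 1e-6 * np.trace(Xm.T @ Xm)
        t = CORAL(lam=lam).fit(Xm, Xs)
        Xm_t = t.transform(Xm)
        target = t.Cs_ - lam * np.eye(18)
        err = np.linalg.norm(Xm_t.T @ Xm_t - target) / np.linalg.norm(t.Cs_)
        assert err < 1e-3

    def test_lambda_validation_and_helper(self, rng):
        X = rng.normal(size=(20, 5))
        with pytest.raises(ValueError, match="positive"):
            CORAL(lam=0.0).fit(X, X)
        assert coral_lambda(X, 1.0) == pytest.approx(np.mean(np.sum(X**2, axis=0)))
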