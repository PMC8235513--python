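"""Calibration-transfer estimators: DS, PDS, PLSDA removal, PLSDA-CT, CORAL.

All five are scikit-learn-style transformers. The first three map *slave*
measurements into the master's response space (or a shared space); CORAL goes
the other way, re-coloring the master data with the slave's second-moment
structure, so with CORAL the classifier is trained on transformed master data
and applied to raw slave data.

Signatures follow the ``fit(X, Y)`` convention of paired-block estimators
(cf. ``sklearn.cross_decomposition``): for DirectStandardization and
PiecewiseDirectStandardization, ``X`` is the slave transfer block and ``Y``
the row-aligned master transfer block.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._pls import PLSModel, pls_fit
from .selection import TransferSet

__all__ = [
    "DirectStandardization",
    "PiecewiseDirectStandardization",
    "PLSDAComponentRemoval",
    "PLSDACalibrationTransfer",
    "CORAL",
    "fit_ds",
    "apply_ds",
    "fit_pds",
    "apply_pds",
    "fit_plsda_removal",
    "fit_plsda_ct",
    "apply_plsda_ct",
    "fit_coral",
    "apply_coral",
]


def _check_pair(X, Y):
    X = check_array(X, dtype=float)
    Y = check_array(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("transfer blocks must be row-aligned")
    return X, Y


class DirectStandardization(TransformerMixin, BaseEstimator):
    """Direct standardization: one linear map from slave to master space.

    Solves ``Xm_ct = Xs_ct B`` for the k x k transfer matrix B with a
    truncated-SVD pseudoinverse, ``B = pinv(Xs_ct) Xm_ct``. With centering
    (default) the map is affine: intercepts absorb the offset component of
    the device difference.

    Parameters
    ----------
    center : fit on mean-centered blocks and store intercepts; ``False``
        reproduces the plain linear form.
    rcond : relative singular-value cutoff of the pseudoinverse.

    Attributes
    ----------
    B_ : (k, k) transfer matrix.
    intercept_ : (k,) offset applied after the matrix product.
    """

    def __init__(self, center: bool = True, rcond: float = 1e-10):
        self.center = center
        self.rcond = rcond

    def fit(self, X, Y):
        X, Y = _check_pair(X, Y)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 transfer samples")
        if np.allclose(X, X[0], atol=1e-12):
            raise ValueError("transfer rows are all identical (degenerate)")
        if self.center:
            xm, ym = X.mean(axis=0), Y.mean(axis=0)
        else:
            xm = np.zeros(X.shape[1])
            ym = np.zeros(Y.shape[1])
        self.B_ = np.linalg.pinv(X - xm, rcond=self.rcond) @ (Y - ym)
        self.intercept_ = ym - xm @ self.B_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "B_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, transform expects {self.n_features_in_}"
            )
        return X @ self.B_ + self.intercept_


class PiecewiseDirectStandardization(TransformerMixin, BaseEstimator):
    """Piecewise direct standardization with local PLS window models.

    Each master variable j is regressed on a sliding window of ``window``
    slave variables centered at j (truncated at the array edges), giving a
    banded transfer matrix; entries outside each column's window are exactly
    zero. ``window`` must be odd, or equal to the number of variables (the
    full window, where PDS coincides with DS on full-rank data).

    Parameters
    ----------
    window : sliding-window width w.
    n_components : latent variables per local PLS model; ``None`` uses the
        full achievable rank of each window (OLS-equivalent).
    center : as in DirectStandardization.

    Attributes
    ----------
    B_ : (k, k) banded transfer matrix.
    intercept_ : (k,) per-variable offsets.
    """

    def __init__(self, window: int = 13, n_components: int | None = 2, center: bool = True):
        self.window = window
        self.n_components = n_components
        self.center = center

    def fit(self, X, Y):
        X, Y = _check_pair(X, Y)
        n, k = X.shape
        w = self.window
        if not 1 <= w <= k:
            raise ValueError(f"window must be in 1..{k}")
        if w % 2 == 0 and w != k:
            raise ValueError("window must be odd (or the full variable count)")
        half = (w - 1) // 2
        B = np.zeros((k, k))
        intercept = np.zeros(k)
        for j in range(k):
            if w == k:
                lo, hi = 0, k
            else:
                lo, hi = max(0, j - half), min(k, j + half + 1)
            cols = np.arange(lo, hi)
            if self.center:
                n_lv = len(cols) if self.n_components is None else min(self.n_components, len(cols))
                n_lv = min(n_lv, n - 1)
                model = pls_fit(X[:, cols], Y[:, j], n_lv, strict=False)
                B[cols, j] = model.coef[:, 0]
                intercept[j] = float(model.y_mean[0] - model.x_mean @ model.coef[:, 0])
            else:
                # literal intercept-free form: least squares through the origin
                B[cols, j] = np.linalg.pinv(X[:, cols], rcond=1e-10) @ Y[:, j]
        self.B_ = B
        self.intercept_ = intercept
        self.n_features_in_ = k
        return self

    def transform(self, X):
        check_is_fitted(self, "B_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, transform expects {self.n_features_in_}"
            )
        return X @ self.B_ + self.intercept_


class PLSDAComponentRemoval(TransformerMixin, BaseEstimator):
    """Remove instrument-membership PLS components from the data.

    A PLS model is fit on the stacked (mean-centered) master and slave
    transfer blocks against a +1/-1 instrument-membership dummy; the subspace
    it predicts is then projected out of any data matrix:
    ``X' = X - X W (P^T W)^{-1} P^T``. The removal is an oblique projection
    and therefore idempotent.

    Parameters
    ----------
    n_components : number of membership components removed (>= 1).

    Attributes
    ----------
    W_, P_ : (k, c) membership PLS weights and loadings.
    mean_ : (k,) centering vector of the stacked transfer data.
    """

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        groups = np.unique(y)
        if len(groups) != 2:
            raise ValueError("membership vector must contain exactly two groups")
        dummy = np.where(y == groups[0], 1.0, -1.0)
        model = pls_fit(X, dummy, self.n_components, strict=True)
        self.W_ = model.W
        self.P_ = model.P
        self.mean_ = model.x_mean
        self._removal_ = np.eye(X.shape[1]) - model.rotations @ model.P.T
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_blocks(cls, Xm, Xs, n_components: int = 1) -> "PLSDAComponentRemoval":
        """Fit from separate master and slave transfer blocks."""
        Xm = np.asarray(Xm, dtype=float)
        Xs = np.asarray(Xs, dtype=float)
        X = np.vstack([Xm, Xs])
        y = np.concatenate([np.ones(len(Xm)), -np.ones(len(Xs))])
        return cls(n_components=n_components).fit(X, y)

    def transform(self, X):
        check_is_fitted(self, "W_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) @ self._removal_ + self.mean_


class PLSDACalibrationTransfer(TransformerMixin, BaseEstimator):
    """PLS score-space transfer (PLSCT, used here with class-membership PLSDA).

    A PLS(-DA) model with ``n_components`` latent variables is built on the
    master training data against the class dummy. Labeled transfer samples
    from both instruments are projected through the master model,

        Tm = (Xm_ct - mean) W (P^T W)^{-1},   T's = (Xs_ct - mean) W (P^T W)^{-1},

    and a c x c score-space map M is estimated by ordinary least squares,
    ``M = (T's^T T's)^{-1} T's^T Tm``. ``transform`` projects new slave data
    and applies M; the downstream classifier operates on these scores. A
    coefficient-mode prediction path (master regression coefficients applied
    directly to slave data, bypassing M) is provided for comparison.

    Attributes
    ----------
    pls_ : fitted master PLSModel.
    M_ : (c, c) score-space alignment matrix.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y, Xm_ct=None, Xs_ct=None, transfer: TransferSet | None = None):
        X = check_array(X, dtype=float)
        if transfer is not None:
            Xm_ct, Xs_ct = transfer.Xm, transfer.Xs
        if Xm_ct is None or Xs_ct is None:
            raise ValueError("labeled transfer blocks Xm_ct/Xs_ct are required")
        Xm_ct, Xs_ct = _check_pair(Xm_ct, Xs_ct)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("master training labels must contain two classes")
        dummy = np.where(y == classes[-1], 1.0, -1.0)
        self.pls_ = pls_fit(X, dummy, self.n_components, strict=True)
        R = self.pls_.rotations
        Tm = (Xm_ct - self.pls_.x_mean) @ R
        Ts = (Xs_ct - self.pls_.x_mean) @ R
        gram = Ts.T @ Ts
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "T's^T T's is singular; reduce n_components or add transfer samples"
            )
        self.M_ = np.linalg.solve(gram, Ts.T @ Tm)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def project_master(self, X):
        """Master-model PLS scores of master-space data (no M applied)."""
        check_is_fitted(self, "M_")
        return self.pls_.scores(check_array(X, dtype=float))

    def transform(self, X):
        """Slave data -> master-aligned score space: ``T' M``."""
        check_is_fitted(self, "M_")
        return self.pls_.scores(check_array(X, dtype=float)) @ self.M_

    def predict_coefficient_mode(self, X):
        """Dummy-response prediction from master coefficients on raw slave data."""
        check_is_fitted(self, "M_")
        return self.pls_.predict(check_array(X, dtype=float))[:, 0]


class CORAL(TransformerMixin, BaseEstimator):
    """Correlation alignment: whiten master data, re-color with slave moments.

    Regularized second-moment matrices ``Cm = Xm^T Xm + lam I`` and
    ``Cs = Xs^T Xs + lam I`` define the alignment ``A = Cm^{-1/2} Cs^{1/2}``
    (symmetric eigendecompositions; eigenvalues clipped at zero before the
    root). ``transform`` maps *master* rows toward the slave distribution, so
    train the classifier on transformed master data and apply it to raw slave
    data. Unsupervised: no labels are used.

    Parameters
    ----------
    lam : regularization strength (> 0), on the scale of the moment-matrix
        diagonal; see :func:`coral_lambda` for the relative-scale grid.

    Attributes
    ----------
    A_ : (k, k) alignment matrix.
    Cm_, Cs_ : regularized second-moment matrices.
    """

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def fit(self, X, Y):
        """X: master block; Y: slave block (row counts may differ)."""
        X = check_array(X, dtype=float)
        Y = check_array(Y, dtype=float)
        if X.shape[1] != Y.shape[1]:
            raise ValueError("master and slave must share the feature space")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        k = X.shape[1]
        self.Cm_ = X.T @ X + self.lam * np.eye(k)
        self.Cs_ = Y.T @ Y + self.lam * np.eye(k)
        self.A_ = _matrix_power(self.Cm_, -0.5) @ _matrix_power(self.Cs_, 0.5)
        self.n_features_in_ = k
        return self

    def transform(self, X):
        check_is_fitted(self, "A_")
        X = check_array(X, dtype=float)
        return X @ self.A_


def _matrix_power(C: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    if power < 0:
        if vals.min() <= 0:
            raise ValueError("matrix is singular; increase the regularization")
        pv = vals ** power
    else:
        pv = vals ** power
    return (vecs * pv) @ vecs.T


def coral_lambda(X: np.ndarray, factor: float) -> float:
    """Absolute lambda from a relative factor x mean diagonal of ``X^T X``."""
    X = np.asarray(X, dtype=float)
    return float(factor * np.mean(np.einsum("ij,ij->j", X, X)))


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators

def fit_ds(ts: TransferSet, **kw) -> DirectStandardization:
    return DirectStandardization(**kw).fit(ts.Xs, ts.Xm)


def apply_ds(t: DirectStandardization, Xs) -> np.ndarray:
    return t.transform(Xs)


def fit_pds(ts: TransferSet, window: int = 13, n_components: int | None = 2, **kw) -> PiecewiseDirectStandardization:
    return PiecewiseDirectStandardization(window=window, n_components=n_components, **kw).fit(ts.Xs, ts.Xm)


def apply_pds(t: PiecewiseDirectStandardization, Xs) -> np.ndarray:
    return t.transform(Xs)


def fit_plsda_removal(Xm, Xs, n_components: int = 1) -> PLSDAComponentRemoval:
    return PLSDAComponentRemoval.from_blocks(Xm, Xs, n_components=n_components)


def fit_plsda_ct(X, y, ts: TransferSet, n_components: int = 2) -> PLSDACalibrationTransfer:
    return PLSDACalibrationTransfer(n_components=n_components).fit(X, y, transfer=ts)


def apply_plsda_ct(t: PLSDACalibrationTransfer, Xs) -> np.ndarray:
    return t.transform(Xs)


def fit_coral(Xm, Xs, lam: float) -> CORAL:
    return CORAL(lam=lam).fit(Xm, Xs)


def apply_coral(t: CORAL, Xm) -> np.ndarray:
    return t.transform(Xm)
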