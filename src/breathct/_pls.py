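"""NIPALS partial least squares, the shared engine behind the transfer methods.

A deliberately small PLS2 implementation: the transfer algorithms need the raw
weight/loading matrices (W, P) and the score projection X W (P^T W)^{-1} in
exactly the textbook orientation, and they must survive degenerate inputs
(zero-residual deflation, responses orthogonal to X) that arise in sliding
windows and one-class transfer sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500
# residual columns with variance below this fraction of the original are
# treated as exhausted (rank reached)
_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS decomposition (mean-centered internally).

    Attributes
    ----------
    W, P : (k, c) weight and X-loading matrices.
    Q : (q, c) Y-loading matrix.
    coef : (k, q) regression coefficients, ``coef = W (P^T W)^{-1} Q^T``.
    x_mean, y_mean : column means removed before fitting.
    """

    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_components: int = field(default=0)

    def __post_init__(self) -> None:
        self.n_components = self.W.shape[1]

    @property
    def rotations(self) -> np.ndarray:
        """``R = W (P^T W)^{-1}`` so that scores ``T = (X - x_mean) R``.

        Uses a pseudoinverse so the degenerate zero model (response
        uncorrelated with X) yields zero scores instead of failing.
        """
        return self.W @ np.linalg.pinv(self.P.T @ self.W)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.rotations

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    *,
    strict: bool = True,
) -> PLSModel:
    """Fit a PLS2 regression of ``Y`` on ``X`` with NIPALS.

    Parameters
    ----------
    X : (n, k) predictor matrix.
    Y : (n, q) response matrix (a 1-D array is treated as one column).
    n_components : number of latent variables to extract.
    strict : if True, raise when ``n_components`` exceeds what the data can
        support; if False, silently stop early at the achievable rank (used by
        the sliding-window models where edge windows lose columns).

    Returns
    -------
    PLSModel with at most ``n_components`` extracted components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"X has {n} rows but Y has {Y.shape[0]}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if strict and n_components > min(n - 1, k):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, k)={min(n - 1, k)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    x_scale0 = float(np.sum(E * E))
    if x_scale0 <= 0.0:
        raise ValueError("X has zero variance; cannot fit PLS")

    n_max = min(n_components, n - 1, k)
    Ws, Ps, Qs = [], [], []
    for _ in range(n_max):
        if np.sum(E * E) <= _RANK_TOL * x_scale0:
            break  # X residual exhausted
        # start u from the F column with the largest remaining variance
        j0 = int(np.argmax(np.sum(F * F, axis=0)))
        u = F[:, j0].copy()
        if np.sum(u * u) <= _RANK_TOL * max(float(np.sum(Y * Y)), 1.0):
            # response residual is numerically zero: perfect fit reached
            break
        w = np.zeros(k)
        for _ in range(_NIPALS_MAX_ITER):
            w_new = E.T @ u
            norm = np.linalg.norm(w_new)
            if norm <= 0.0:
                break
            w_new /= norm
            t = E @ w_new
            tt = float(t @ t)
            if tt <= 0.0:
                break
            q = F.T @ t / tt
            qn = np.linalg.norm(q)
            u = F @ q / (qn * qn) if qn > 0 else u
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = E @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL * x_scale0:
            break
        p = E.T @ t / tt
        q = F.T @ t / tt
        E = E - np.outer(t, p)
        F = F - np.outer(t, q)
        Ws.append(w)
        Ps.append(p)
        Qs.append(q)

    if not Ws:
        # Y carries no X-correlated signal at all (e.g. orthogonal response):
        # the regression limit is a zero-coefficient model.
        cross = np.linalg.norm(E.T @ F)
        scale = np.sqrt(np.sum(E * E) * np.sum(F * F))
        if scale == 0.0 or cross <= 1e-10 * scale:
            q = Y.shape[1]
            zero = np.zeros((k, 1))
            return PLSModel(
                W=zero, P=zero, Q=np.zeros((q, 1)), coef=np.zeros((k, q)),
                x_mean=x_mean, y_mean=y_mean,
            )
        raise ValueError("could not extract any PLS component (degenerate X)")
    if strict and len(Ws) < n_components:
        raise ValueError(
            f"only {len(Ws)} of {n_components} components are supported by "
            "the data (rank deficiency); reduce n_components"
        )
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    Q = np.column_stack(Qs)
    coef = W @ np.linalg.pinv(P.T @ W) @ Q.T
    return PLSModel(W=W, P=P, Q=Q, coef=coef, x_mean=x_mean, y_mean=y_mean)
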