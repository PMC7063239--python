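"""Latent-variable regression between score spaces.

Partial least squares (PLS) regression links the score space of one shape
model to another (the denoising pipeline's central operation), canonical
correlation analysis (CCA) measures the association between shape scores
and a binary factor, and a one-component PLSR quantifies the share of shape
variance attributable to that factor.

Columns are mean-centered but not variance-scaled by default: PC scores
carry their eigenvalue-weighted scale, so "variance" below refers to shape
space variance in mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression


@dataclass(eq=False)
class PLSModel:
    """Centered linear map fitted by PLS with ``k`` latent components.

    ``predict`` applies ``y = (x - x_mean) @ coef + y_mean``; ``coef`` is
    derived from the fitted estimator so the stored matrix form and the
    estimator agree exactly.
    """

    k: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray
    x_weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        single = x.ndim == 1
        y = (np.atleast_2d(x) - self.x_mean) @ self.coef + self.y_mean
        return y[0] if single else y


@dataclass
class CCAResult:
    """Single canonical pair between shape scores and a 1-D label."""

    r: float
    x_direction: np.ndarray
    y_direction: float = 1.0


def fit_pls(X: np.ndarray, Y: np.ndarray, k: int, scale: bool = False) -> PLSModel:
    """Fit a k-component PLS regression from score matrix X to Y."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if not 1 <= k <= min(rank, X.shape[1]):
        raise ValueError(f"k={k} outside [1, rank(X)={rank}]")
    est = PLSRegression(n_components=k, scale=scale, max_iter=1000, tol=1e-10)
    est.fit(X, Y)
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    # derive the centered coefficient matrix from the estimator itself,
    # insulating the stored form from sklearn's coef_ layout conventions
    basis = x_mean + np.eye(X.shape[1])
    coef = est.predict(basis) - est.predict(x_mean[None, :])
    return PLSModel(k=k, x_mean=x_mean, y_mean=y_mean, coef=coef,
                    x_weights=est.x_weights_.copy(),
                    y_loadings=est.y_loadings_.copy())


def predict(model: PLSModel, x: np.ndarray) -> np.ndarray:
    return model.predict(x)


def fit_cca(X: np.ndarray, y: np.ndarray) -> CCAResult:
    """Canonical correlation between score columns and a binary label.

    With a one-dimensional label the canonical pair is unique: the canonical
    direction is the least-squares discriminant ``Cov(X)^-1 Cov(X, y)`` and
    ``r`` the multiple correlation of the fit.  Invariant to any invertible
    affine re-coding of the labels.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).reshape(-1)
    if X.shape[0] != y.shape[0]:
        raise ValueError("row count mismatch")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    w, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ w
    denom = np.linalg.norm(fitted) * np.linalg.norm(yc)
    r = 0.0 if denom == 0 else float(np.clip(fitted @ yc / denom, 0.0, 1.0))
    norm = np.linalg.norm(w)
    direction = w / norm if norm > 0 else w
    return CCAResult(r=r, x_direction=direction)


def plsr_explained_variance(X: np.ndarray, y: np.ndarray,
                            column_weights: np.ndarray | None = None) -> float:
    """Percent of (eigenvalue-weighted) score variance explained by a label.

    Equivalent to a one-component PLSR with the label as sole predictor,
    which for a univariate predictor reduces to per-column least squares on
    the label.  With unwhitened PC scores the column variances already equal
    the model eigenvalues, so the default (no extra weights) measures shape
    space variance; ``column_weights`` allows re-weighting, e.g. when scores
    were whitened upstream.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).reshape(-1)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    vy = yc @ yc
    beta = xc.T @ yc / vy
    xhat = np.outer(yc, beta)
    w = np.ones(X.shape[1]) if column_weights is None else np.asarray(column_weights, float)
    num = (w * (xhat ** 2).sum(axis=0)).sum()
    den = (w * (xc ** 2).sum(axis=0)).sum()
    if den == 0:
        return 0.0
    return float(100.0 * num / den)
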