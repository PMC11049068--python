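"""PLS1 regression with leave-one-out cross-validation.

The fit is mean-centered NIPALS PLS1 (no variance scaling), the dominant
convention in NIR chemometrics.  One fit pass yields the regression
coefficient vector for *every* component count ``1..A`` — the coefficient
path — which makes RMSECV-versus-components curves and the repeated inner
fits of wavelength-selection loops cheap: cross-validation refits each
training fold once, not once per component count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ValidationError


def _center(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def coefficient_paths(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """Regression-coefficient paths of centered PLS1.

    Returns ``B`` of shape ``(a_max, p)`` where ``B[a-1]`` maps *centered*
    spectra to *centered* response for a model with ``a`` components.  If
    the signal deflates to zero before ``a_max`` components the remaining
    rows repeat the last valid coefficients.
    """
    Xc, yc, _, _ = _center(np.asarray(X, float), np.asarray(y, float))
    n, p = Xc.shape
    if a_max < 1 or a_max > min(n - 1, p):
        raise ValidationError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.allclose(yc, 0.0):
        raise ValidationError("response y has zero variance")

    B = np.zeros((a_max, p))
    R = np.zeros((p, a_max))   # R = W (P'W)^{-1}, built incrementally
    P = np.zeros((p, a_max))
    beta = np.zeros(p)
    Xd, yd = Xc, yc.copy()
    for a in range(a_max):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= np.finfo(float).eps * max(n, p):
            B[a:] = beta   # signal exhausted; freeze the path
            return B
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            B[a:] = beta
            return B
        pl = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - q * t
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        R[:, a] = r
        P[:, a] = pl
        beta = beta + q * r
        B[a] = beta
    return B


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 model: prediction is ``y_mean + (x - x_mean) @ coef``."""

    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    n_components: int
    wavelength_subset: np.ndarray | None = None
    coefficient_path: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, float))
        if X_new.shape[1] != self.x_mean.shape[0]:
            raise ValidationError(
                f"X has {X_new.shape[1]} channels, model was fit on "
                f"{self.x_mean.shape[0]}")
        return self.y_mean + (X_new - self.x_mean) @ self.coefficients


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int,
            wavelength_subset: np.ndarray | None = None,
            keep_path: bool = False) -> PLSModel:
    """Fit mean-centered PLS1 with ``n_components`` latent variables."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValidationError("X must be (n, p) and y length n")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("X and y must be finite")
    B = coefficient_paths(X, y, n_components)
    subset = None if wavelength_subset is None else np.asarray(
        wavelength_subset, dtype=int)
    return PLSModel(
        x_mean=X.mean(axis=0), y_mean=float(y.mean()),
        coefficients=B[n_components - 1], n_components=n_components,
        wavelength_subset=subset,
        coefficient_path=B if keep_path else None,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    return model.predict(X_new)


@dataclass(frozen=True)
class CVResult:
    rmsecv_by_components: np.ndarray
    optimal_components: int

    @property
    def min_rmsecv(self) -> float:
        return float(self.rmsecv_by_components[self.optimal_components - 1])


def _fold_indices(n: int, folds: int | None) -> list[np.ndarray]:
    """Deterministic validation folds: LOO if folds is None, else round-robin
    assignment by sample order (sample i -> fold i mod k)."""
    if folds is None:
        return [np.array([i]) for i in range(n)]
    if not (2 <= folds <= n):
        raise ValidationError(f"folds must be in [2, {n}]")
    assign = np.arange(n) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


def cv_rmsecv(X: np.ndarray, y: np.ndarray, a_max: int,
              folds: int | None = None) -> CVResult:
    """RMSECV for every component count ``1..a_max``.

    ``folds=None`` gives leave-one-out cross-validation: each calibration
    sample is held out once, the model refit on the rest and the held-out
    prediction error accumulated.  The optimal component count is the
    argmin of the curve; ties break toward fewer components.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("cross-validation needs n >= 3")
    fold_sets = _fold_indices(n, folds)
    max_train = min(len(np.setdiff1d(np.arange(n), f)) for f in fold_sets)
    a_cap = min(a_max, max_train - 1, p)
    if a_cap < 1:
        raise ValidationError("too few samples for even one component")

    sse = np.zeros(a_cap)
    for val in fold_sets:
        train = np.setdiff1d(np.arange(n), val)
        Xt, yt = X[train], y[train]
        if np.ptp(yt) == 0:
            # constant training response: the model is its mean
            resid = np.broadcast_to(
                (yt.mean() - y[val])[:, None], (val.size, a_cap))
        else:
            B = coefficient_paths(Xt, yt, a_cap)
            resid = (X[val] - Xt.mean(axis=0)) @ B.T + yt.mean() - y[val][:, None]
        sse += (resid ** 2).sum(axis=0)
    rmsecv = np.sqrt(sse / n)
    # prefer parsimony: the smallest A whose RMSECV ties the minimum to
    # within numerical noise (scaled by the curve's magnitude)
    cutoff = rmsecv.min() + 1e-8 * rmsecv.max()
    optimal = int(np.argmax(rmsecv <= cutoff)) + 1
    return CVResult(rmsecv_by_components=rmsecv, optimal_components=optimal)


def loocv_rmsecv(X: np.ndarray, y: np.ndarray, a_max: int) -> CVResult:
    """Leave-one-out RMSECV curve (see :func:`cv_rmsecv`)."""
    return cv_rmsecv(X, y, a_max, folds=None)
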