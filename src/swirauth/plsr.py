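"""PLS1 regression of adulterant concentration on spectra.

NIPALS-style sequential extraction of latent factors on column-centered data
(centering only, no per-band scaling — the spectroscopy convention). The
factor count is chosen by leave-one-out cross-validation at the minimum
RMSECV; because NIPALS is incremental, one fit per fold yields the held-out
prediction for every candidate factor count at once. The fitted model is
collapsed to an affine map (beta vector + intercept), which is what the
per-pixel chemical mapping consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn.base import BaseEstimator, RegressorMixin, clone

from .containers import SpectralSet
from .preprocess import SpectralPreprocessor

_WEIGHT_TOL = 1e-12


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectralSet):
        return X.intensities
    return np.atleast_2d(np.asarray(X, dtype=float))


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Sequential NIPALS factor extraction for a single response.

    Returns weights W, x-loadings P and y-loadings q for each factor.
    Raises when the residual weight vector vanishes (rank exhausted).
    """
    n, j = Xc.shape
    W = np.zeros((j, n_components))
    P = np.zeros((j, n_components))
    q = np.zeros(n_components)
    X_res = Xc.copy()
    y_res = yc.copy()
    scale = np.linalg.norm(Xc) * np.linalg.norm(yc) + _WEIGHT_TOL
    for a in range(n_components):
        w = X_res.T @ y_res
        nw = np.linalg.norm(w)
        if nw <= _WEIGHT_TOL * scale:
            raise ValueError(
                f"factor {a + 1}: vanishing weight norm (rank deficiency); "
                f"reduce the factor count"
            )
        w /= nw
        t = X_res @ w
        tt = float(t @ t)
        p = X_res.T @ t / tt
        qa = float(y_res @ t) / tt
        X_res -= np.outer(t, p)
        y_res -= qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
    return W, P, q


def _beta_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray, A: int) -> np.ndarray:
    """Regression vector for the first A factors: W (P'W)^-1 q."""
    Wa, Pa, qa = W[:, :A], P[:, :A], q[:A]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


class PLS1Regression(RegressorMixin, BaseEstimator):
    """Partial least squares regression with a single response.

    Parameters
    ----------
    n_components : int or "auto"
        Latent factor count A; "auto" selects it by leave-one-out RMSECV up
        to ``max_components``.
    max_components : int
        Search ceiling for automatic selection.
    preprocessor : SpectralPreprocessor or None
        Optional pretreatment fitted on the calibration set and applied to
        every sample before regression (carried by the model).

    Fitted attributes: ``coef_`` (beta vector), ``intercept_``,
    ``x_mean_``/``y_mean_``, ``x_weights_``/``x_loadings_``/``y_loadings_``,
    ``n_components_``, and ``rmsecv_`` when selection ran.
    """

    def __init__(self, n_components=2, max_components=15, preprocessor=None):
        self.n_components = n_components
        self.max_components = max_components
        self.preprocessor = preprocessor

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if np.all(y == y[0]):
            raise ValueError("response is constant; nothing to regress")
        if self.preprocessor is not None:
            self.preprocessor_ = clone(self.preprocessor).fit(X)
            X = self.preprocessor_.transform(X)
        else:
            self.preprocessor_ = None

        self.rmsecv_ = None
        if self.n_components == "auto":
            rmsecv, A = _loo_cv_matrix(X, y, self.max_components)
            self.rmsecv_ = rmsecv
            self.n_components_ = A
        else:
            A = int(self.n_components)
            if A < 1:
                raise ValueError("n_components must be >= 1")
            self.n_components_ = A
        n = X.shape[0]
        if self.n_components_ > min(n - 1, X.shape[1]):
            raise ValueError("n_components exceeds min(n-1, bands)")

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        W, P, q = _nipals(X - self.x_mean_, y - self.y_mean_, self.n_components_)
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        self.coef_ = _beta_from_factors(W, P, q, self.n_components_)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = self.x_mean_.size
        fitted = self.intercept_ + X @ self.coef_
        self.fit_report_ = evaluate(y, fitted)
        return self

    def predict(self, X) -> np.ndarray:
        """intercept + X . beta (no clipping; the mapping layer clips)."""
        X = _as_matrix(X)
        if self.preprocessor_ is not None:
            X = self.preprocessor_.transform(X)
        if X.shape[1] != self.coef_.size:
            raise ValueError(f"band count {X.shape[1]} does not match model ({self.coef_.size})")
        return self.intercept_ + X @ self.coef_

    # ------------------------------------------------------------- persist
    def save(self, path) -> Path:
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".npz")
        np.savez(
            sidecar,
            coef=self.coef_,
            x_mean=self.x_mean_,
            x_weights=self.x_weights_,
            x_loadings=self.x_loadings_,
            y_loadings=self.y_loadings_,
        )
        meta = {
            "kind": "pls1",
            "n_components": int(self.n_components_),
            "intercept": float(self.intercept_),
            "y_mean": self.y_mean_,
            "n_features_in": int(self.n_features_in_),
            "preprocess": None if self.preprocessor_ is None else self.preprocessor_.to_dict(),
            "rmsecv": None if self.rmsecv_ is None else [float(v) for v in self.rmsecv_],
            "sec": float(self.fit_report_.se),
            "r2_cal": float(self.fit_report_.r2),
            "sidecar": sidecar.name,
        }
        path.write_text(yaml.safe_dump(meta, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "PLS1Regression":
        path = Path(path)
        meta = yaml.safe_load(path.read_text())
        if meta.get("kind") != "pls1":
            raise ValueError(f"{path} is not a PLS1 model file")
        arrays = np.load(path.parent / meta["sidecar"])
        model = cls(n_components=meta["n_components"])
        model.preprocessor_ = (
            None
            if meta["preprocess"] is None
            else SpectralPreprocessor.from_dict(meta["preprocess"])
        )
        model.n_components_ = int(meta["n_components"])
        model.coef_ = arrays["coef"]
        model.x_mean_ = arrays["x_mean"]
        model.x_weights_ = arrays["x_weights"]
        model.x_loadings_ = arrays["x_loadings"]
        model.y_loadings_ = arrays["y_loadings"]
        model.intercept_ = float(meta["intercept"])
        model.y_mean_ = float(meta["y_mean"])
        model.n_features_in_ = int(meta["n_features_in"])
        model.rmsecv_ = meta["rmsecv"]
        return model


# ---------------------------------------------------------------------------
# model selection and reporting


def _loo_cv_matrix(X: np.ndarray, y: np.ndarray, A_max: int):
    """Leave-one-out RMSECV for A = 1..A_max on a plain matrix."""
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    A_max = int(min(A_max, n - 2, X.shape[1]))
    if A_max < 1:
        raise ValueError("no admissible factor count")
    preds = np.full((n, A_max), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        Xt, yt = X[keep], y[keep]
        xm, ym = Xt.mean(axis=0), yt.mean()
        a_fit = A_max
        while a_fit >= 1:
            try:
                W, P, q = _nipals(Xt - xm, yt - ym, a_fit)
                break
            except ValueError:
                a_fit -= 1
        if a_fit < 1:
            raise ValueError(f"fold {i}: rank-deficient calibration subset")
        for A in range(1, a_fit + 1):
            beta = _beta_from_factors(W, P, q, A)
            preds[i, A - 1] = ym + (X[i] - xm) @ beta
        preds[i, a_fit:] = preds[i, a_fit - 1]
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    A_selected = int(np.argmin(rmsecv)) + 1  # argmin takes the first = smallest A on ties
    return rmsecv, A_selected


def loo_cv(X, y, A_max: int, preprocessor: SpectralPreprocessor | None = None):
    """Leave-one-out RMSECV curve and the selected factor count.

    The optional preprocessor is refitted inside every fold on the n-1
    calibration rows, so held-out samples never inform the transform.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if preprocessor is not None:
        n = X.shape[0]
        if n < 3:
            raise ValueError("leave-one-out needs at least 3 samples")
        A_cap = int(min(A_max, n - 2))
        preds = np.full((n, A_cap), np.nan)
        for i in range(n):
            keep = np.arange(n) != i
            pp = clone(preprocessor).fit(X[keep])
            Xt = pp.transform(X[keep])
            xi = pp.transform(X[i : i + 1])[0]
            yt = y[keep]
            xm, ym = Xt.mean(axis=0), yt.mean()
            a_fit = min(A_cap, Xt.shape[1])
            while a_fit >= 1:
                try:
                    W, P, q = _nipals(Xt - xm, yt - ym, a_fit)
                    break
                except ValueError:
                    a_fit -= 1
            if a_fit < 1:
                raise ValueError(f"fold {i}: rank-deficient calibration subset")
            for A in range(1, a_fit + 1):
                beta = _beta_from_factors(W, P, q, A)
                preds[i, A - 1] = ym + (xi - xm) @ beta
            preds[i, a_fit:] = preds[i, a_fit - 1]
        rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
        return rmsecv, int(np.argmin(rmsecv)) + 1
    return _loo_cv_matrix(X, y, A_max)


@dataclass
class RegressionReport:
    """RMSE-based standard error and coefficient of determination."""

    r2: float
    se: float
    n: int
    residuals: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegressionReport(r2={self.r2:.4f}, se={self.se:.3f}%, n={self.n})"


def evaluate(y_true, y_pred) -> RegressionReport:
    """Standard error (root mean squared residual) and R^2 about the
    evaluated set's own mean."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("prediction/reference length mismatch")
    if y_true.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    residuals = y_true - y_pred
    se = float(np.sqrt(np.mean(residuals**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else np.nan
    return RegressionReport(r2=r2, se=se, n=y_true.size, residuals=residuals)
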