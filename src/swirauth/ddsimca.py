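"""Data-driven SIMCA one-class classification.

The target class (pure almond spectra) is modelled by a PCA subspace of A
components. Each sample is summarised by two distances: the score distance
h (leverage: eigenvalue-normalized squared score distance from the class
center inside the subspace) and the orthogonal distance v (squared residual
norm outside it). Both are treated as scaled chi-square variables whose
degrees of freedom Nh, Nv are estimated from the training distances by the
method of moments, giving a single total distance

    c = Nh * h / h0 + Nv * v / v0        (h0, v0: training means)

that is approximately chi-square with Nh + Nv degrees of freedom. The
acceptance boundary is the 1 - alpha chi-square quantile of c; the outlier
boundary uses the order-statistic-corrected level (1 - gamma)^(1/n) so a
clean training set of size n triggers a false outlier call with probability
about gamma. Training samples between the two boundaries are "extreme";
prediction accepts a sample iff c <= c_crit (boundaries inclusive).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import chi2
from sklearn.base import BaseEstimator, OutlierMixin, clone

from .containers import SpectralSet
from .preprocess import SpectralPreprocessor

logger = logging.getLogger(__name__)

DOF_CAP = 250


def dof_estimate(d: np.ndarray) -> int:
    """Chi-square degrees of freedom of a distance sample, by moments.

    For X ~ s * chi2(N): 2*mean(X)^2 / var(X) = N, independent of the scale
    s. Rounded to the nearest integer and clipped to [1, 250]; a zero-variance
    sample returns the cap with a warning (distances effectively
    deterministic).
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 distances to estimate degrees of freedom")
    mean = d.mean()
    if mean <= 0:
        raise ValueError("distances must have positive mean")
    var = d.var(ddof=1)
    if var == 0:
        logger.warning("zero-variance distances: degrees of freedom capped at %d", DOF_CAP)
        return DOF_CAP
    return int(np.clip(round(2.0 * mean * mean / var), 1, DOF_CAP))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectralSet):
        return X.intensities
    return np.atleast_2d(np.asarray(X, dtype=float))


def _specimen_ids(X, n: int):
    if isinstance(X, SpectralSet):
        return X.meta["specimen_id"].tolist()
    return [f"s{i}" for i in range(n)]


class DDSimca(OutlierMixin, BaseEstimator):
    """One-class classifier for the target (pure) class.

    Parameters
    ----------
    n_components : int
        Number of PCA factors A retained for the class subspace.
    alpha : float
        Significance level of the acceptance boundary (default 0.01).
    gamma : float
        Outlier level; the outlier cutoff uses the (1-gamma)^(1/n)
        order-statistic correction (default 0.01).
    preprocessor : SpectralPreprocessor or None
        Optional pretreatment fitted on the training set and applied to every
        sample before distance computation; carried by the model so unknowns
        are always transformed consistently.

    Fitted attributes (trailing underscore) include the class center, the
    orthonormal loadings, per-component eigenvalues, distance normalizers
    h0_/v0_, estimated degrees of freedom dof_score_/dof_orth_, the cutoffs
    c_crit_/c_out_, and the training distance records.
    """

    def __init__(self, n_components=2, alpha=0.01, gamma=0.01, preprocessor=None):
        self.n_components = n_components
        self.alpha = alpha
        self.gamma = gamma
        self.preprocessor = preprocessor

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        if not 0 < self.gamma <= self.alpha < 0.5:
            raise ValueError("require 0 < gamma <= alpha < 0.5")
        X = _as_matrix(X)
        if self.preprocessor is not None:
            self.preprocessor_ = clone(self.preprocessor).fit(X)
            X = self.preprocessor_.transform(X)
        else:
            self.preprocessor_ = None
        n, j = X.shape
        A = int(self.n_components)
        if not 1 <= A < n:
            raise ValueError("need 1 <= n_components < n_train")
        self.center_ = X.mean(axis=0)
        Xc = X - self.center_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(n, j) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if A >= rank:
            raise ValueError(
                f"n_components={A} must be below the rank {rank} of the centered matrix"
            )
        self.loadings_ = Vt[:A].T
        self.eigenvalues_ = s[:A] ** 2 / (n - 1)
        h, v = self._raw_distances(Xc)
        self.h0_ = float(h.mean())
        self.v0_ = float(v.mean())
        if self.v0_ == 0:
            raise ValueError("orthogonal distances vanish: over-fitted basis")
        self.dof_score_ = dof_estimate(h)
        self.dof_orth_ = dof_estimate(v)
        ndof = self.dof_score_ + self.dof_orth_
        self.c_crit_ = float(chi2.ppf(1.0 - self.alpha, ndof))
        self.c_out_ = float(chi2.ppf((1.0 - self.gamma) ** (1.0 / n), ndof))
        self.n_train_ = n
        self.n_features_in_ = j
        c = self.dof_score_ * h / self.h0_ + self.dof_orth_ * v / self.v0_
        self.training_distances_ = pd.DataFrame(
            {
                "specimen_id": [f"t{i}" for i in range(n)],
                "h": h,
                "v": v,
                "c": c,
                "decision": self._training_decision(c),
            }
        )
        return self

    def _raw_distances(self, Xc: np.ndarray):
        T = Xc @ self.loadings_
        h = np.sum(T**2 / self.eigenvalues_, axis=1)
        resid = Xc - T @ self.loadings_.T
        v = np.sum(resid**2, axis=1)
        return h, v

    def _training_decision(self, c: np.ndarray) -> np.ndarray:
        out = np.where(c > self.c_out_, "outlier", np.where(c > self.c_crit_, "extreme", "regular"))
        return out

    # ------------------------------------------------------------ distances
    def distances(self, X) -> pd.DataFrame:
        """Score/orthogonal/total distances of new samples against the fitted
        model (no refitting)."""
        ids = _specimen_ids(X, _as_matrix(X).shape[0])
        X = _as_matrix(X)
        if self.preprocessor_ is not None:
            X = self.preprocessor_.transform(X)
        if X.shape[1] != self.center_.size:
            raise ValueError(
                f"band count {X.shape[1]} does not match model ({self.center_.size})"
            )
        h, v = self._raw_distances(X - self.center_)
        c = self.dof_score_ * h / self.h0_ + self.dof_orth_ * v / self.v0_
        return pd.DataFrame({"specimen_id": ids, "h": h, "v": v, "c": c})

    def classify(self, X) -> pd.DataFrame:
        """Distance records with accepted/rejected decisions (c <= c_crit
        accepted; the boundary is inside)."""
        rec = self.distances(X)
        rec["decision"] = np.where(rec["c"] <= self.c_crit_, "accepted", "rejected")
        return rec

    def predict(self, X) -> np.ndarray:
        """Scikit-learn outlier convention: +1 accepted, -1 rejected."""
        rec = self.classify(X)
        return np.where(rec["decision"] == "accepted", 1, -1)

    def decision_function(self, X) -> np.ndarray:
        """Positive inside the acceptance area, negative outside."""
        return self.c_crit_ - self.distances(X)["c"].to_numpy()

    def score_samples(self, X) -> np.ndarray:
        return -self.distances(X)["c"].to_numpy()

    # --------------------------------------------------------- diagnostics
    def extreme_plot_data(self, X=None, levels=None) -> pd.DataFrame:
        """Expected vs observed extreme counts over significance levels.

        For each level a: expected = a*n, observed = #{c > chi2 quantile at
        1-a}, with the +/- 2*sqrt(a*n*(1-a)) tolerance envelope.
        """
        if X is None:
            c = self.training_distances_["c"].to_numpy()
        else:
            c = self.distances(X)["c"].to_numpy()
        if levels is None:
            levels = np.linspace(0.005, 0.25, 50)
        levels = np.asarray(levels, dtype=float)
        n = c.size
        ndof = self.dof_score_ + self.dof_orth_
        cutoffs = chi2.ppf(1.0 - levels, ndof)
        observed = (c[None, :] > cutoffs[:, None]).sum(axis=1)
        expected = levels * n
        envelope = 2.0 * np.sqrt(levels * n * (1.0 - levels))
        return pd.DataFrame(
            {
                "level": levels,
                "expected_extremes": expected,
                "observed_extremes": observed,
                "envelope": envelope,
            }
        )

    # ------------------------------------------------------------- persist
    def save(self, path) -> Path:
        """YAML metadata plus an .npz sidecar for the matrices."""
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".npz")
        np.savez(
            sidecar,
            center=self.center_,
            loadings=self.loadings_,
            eigenvalues=self.eigenvalues_,
        )
        meta = {
            "kind": "ddsimca",
            "n_components": int(self.n_components),
            "alpha": float(self.alpha),
            "gamma": float(self.gamma),
            "h0": self.h0_,
            "v0": self.v0_,
            "dof_score": int(self.dof_score_),
            "dof_orth": int(self.dof_orth_),
            "c_crit": self.c_crit_,
            "c_out": self.c_out_,
            "n_train": int(self.n_train_),
            "n_features_in": int(self.n_features_in_),
            "preprocess": None if self.preprocessor_ is None else self.preprocessor_.to_dict(),
            "sidecar": sidecar.name,
        }
        path.write_text(yaml.safe_dump(meta, sort_keys=True))
        return path

    @classmethod
    def load(cls, path) -> "DDSimca":
        path = Path(path)
        meta = yaml.safe_load(path.read_text())
        if meta.get("kind") != "ddsimca":
            raise ValueError(f"{path} is not a DD-SIMCA model file")
        arrays = np.load(path.parent / meta["sidecar"])
        model = cls(
            n_components=meta["n_components"], alpha=meta["alpha"], gamma=meta["gamma"]
        )
        model.preprocessor_ = (
            None
            if meta["preprocess"] is None
            else SpectralPreprocessor.from_dict(meta["preprocess"])
        )
        model.center_ = arrays["center"]
        model.loadings_ = arrays["loadings"]
        model.eigenvalues_ = arrays["eigenvalues"]
        model.h0_ = float(meta["h0"])
        model.v0_ = float(meta["v0"])
        model.dof_score_ = int(meta["dof_score"])
        model.dof_orth_ = int(meta["dof_orth"])
        model.c_crit_ = float(meta["c_crit"])
        model.c_out_ = float(meta["c_out"])
        model.n_train_ = int(meta["n_train"])
        model.n_features_in_ = int(meta["n_features_in"])
        model.training_distances_ = None
        return model


def select_factors(
    X_target,
    A_max: int,
    alpha: float = 0.01,
    gamma: float = 0.01,
    preprocessor: SpectralPreprocessor | None = None,
) -> int:
    """Choose the factor count whose training extreme count best matches its
    expectation alpha*n (type-I-error equality); ties go to fewer factors.
    """
    X = _as_matrix(X_target)
    n = X.shape[0]
    if A_max >= n:
        raise ValueError("A_max must be below the training size")
    best_a, best_gap = None, np.inf
    for A in range(1, A_max + 1):
        try:
            model = DDSimca(
                n_components=A, alpha=alpha, gamma=gamma, preprocessor=preprocessor
            ).fit(X)
        except ValueError:
            break  # exceeded the rank of the centered matrix
        observed = int((model.training_distances_["c"] > model.c_crit_).sum())
        gap = abs(observed - alpha * n)
        if gap < best_gap:
            best_a, best_gap = A, gap
    if best_a is None:
        raise ValueError("no factor count could be fitted")
    return best_a
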