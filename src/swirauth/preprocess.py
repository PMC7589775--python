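"""Row-wise spectral pretreatments.

The evaluated set of chemometric pretreatments: mean/max/range normalization,
standard normal variate (SNV), multiplicative scatter correction (MSC),
Savitzky-Golay smoothing and first/second derivatives, plus the raw identity.
All are per-spectrum transforms except MSC, whose reference spectrum is
learned from the calibration set only, so validation data can never leak into
the fitted state.

Savitzky-Golay filtering is applied in 'valid' mode: edge bands where the
full window does not fit are dropped (the band axis shrinks by window-1) so
derivative semantics stay exact; derivatives are per band index.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpectralSet

METHODS = (
    "raw",
    "mean_norm",
    "max_norm",
    "range_norm",
    "snv",
    "msc",
    "sg_smooth",
    "sg_first",
    "sg_second",
)

_SG_DERIV = {"sg_smooth": 0, "sg_first": 1, "sg_second": 2}


def sg_coefficients(window: int, polyorder: int, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial-derivative kernel.

    Returned in natural (dot-product) order: output[i] = kernel . x[window
    centered at i]. The deriv=0 kernel sums to 1; derivative kernels sum to 0.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if not window > polyorder:
        raise ValueError("window must exceed polyorder")
    if not polyorder >= deriv:
        raise ValueError("polyorder must be >= derivative order")
    return savgol_coeffs(window, polyorder, deriv=deriv, use="dot")


def _sg_filter_valid(X: np.ndarray, window: int, polyorder: int, deriv: int) -> np.ndarray:
    kernel = sg_coefficients(window, polyorder, deriv)
    # sliding-window dot product along the band axis, valid region only
    windows = np.lib.stride_tricks.sliding_window_view(X, window, axis=-1)
    return windows @ kernel


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer over (n_spectra, n_bands) matrices.

    Parameters
    ----------
    method : str
        One of :data:`METHODS`.
    window, polyorder : int
        Savitzky-Golay settings (only used by the sg_* methods). Defaults
        (11, 2) suit the ~5.8 nm band spacing of the acquisition grid.
    """

    def __init__(self, method: str = "raw", window: int = 11, polyorder: int = 2):
        self.method = method
        self.window = window
        self.polyorder = polyorder

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y=None):
        X = self._validate(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty calibration set")
        self.n_features_in_ = X.shape[1]
        if self.method == "msc":
            self.reference_ = X.mean(axis=0)
        else:
            self.reference_ = None
        return self

    def _validate(self, X) -> np.ndarray:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in _SG_DERIV:
            if self.window % 2 == 0 or self.window < 5:
                raise ValueError("SG window must be odd and >= 5")
            if self.polyorder < 2 or self.polyorder >= self.window:
                raise ValueError("SG polyorder must satisfy 2 <= polyorder < window")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.method in _SG_DERIV and X.shape[1] < self.window:
            raise ValueError("fewer bands than the SG window")
        return X

    # -- application --------------------------------------------------------
    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        if not hasattr(self, "n_features_in_"):
            raise ValueError("preprocessor is not fitted")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"band count {X.shape[1]} != fitted band count {self.n_features_in_}"
            )
        m = self.method
        if m == "raw":
            return X.copy()
        if m == "mean_norm":
            denom = X.mean(axis=1, keepdims=True)
            if np.any(denom == 0):
                raise ValueError("mean normalization: zero-mean spectrum")
            return X / denom
        if m == "max_norm":
            denom = X.max(axis=1, keepdims=True)
            if np.any(denom == 0):
                raise ValueError("max normalization: zero-max spectrum")
            return X / denom
        if m == "range_norm":
            lo = X.min(axis=1, keepdims=True)
            rng = X.max(axis=1, keepdims=True) - lo
            if np.any(rng == 0):
                raise ValueError("range normalization: constant spectrum")
            return (X - lo) / rng
        if m == "snv":
            sd = X.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError("SNV: constant spectrum has zero variance")
            return (X - X.mean(axis=1, keepdims=True)) / sd
        if m == "msc":
            a, b = self._msc_coefficients(X)
            if np.any(np.abs(b) < 1e-8):
                raise ValueError("MSC: vanishing scatter slope")
            return (X - a[:, None]) / b[:, None]
        return _sg_filter_valid(X, self.window, self.polyorder, _SG_DERIV[m])

    def _msc_coefficients(self, X: np.ndarray):
        """Per-row least squares x ~ a + b * reference."""
        r = self.reference_
        rc = r - r.mean()
        denom = float(rc @ rc)
        if denom == 0:
            raise ValueError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
        a = X.mean(axis=1) - b * r.mean()
        return a, b

    def valid_rows(self, X) -> np.ndarray:
        """Boolean mask of rows the transform is defined for (used by the
        per-pixel mapping stage to drop degenerate pixel spectra)."""
        X = self._validate(X)
        m = self.method
        if m == "mean_norm":
            return X.mean(axis=1) != 0
        if m == "max_norm":
            return X.max(axis=1) != 0
        if m == "range_norm":
            return X.max(axis=1) != X.min(axis=1)
        if m == "snv":
            return X.std(axis=1, ddof=1) != 0
        if m == "msc":
            _, b = self._msc_coefficients(X)
            return np.abs(b) >= 1e-8
        return np.ones(X.shape[0], dtype=bool)

    def output_wavelengths(self, wavelengths) -> np.ndarray:
        """Wavelengths surviving the transform (SG drops window//2 per edge)."""
        lam = np.asarray(wavelengths, dtype=float)
        if self.method in _SG_DERIV:
            half = self.window // 2
            return lam[half:-half]
        return lam

    # -- SpectralSet convenience -------------------------------------------
    def fit_spectral_set(self, sset: SpectralSet) -> "SpectralPreprocessor":
        return self.fit(sset.intensities)

    def transform_spectral_set(self, sset: SpectralSet) -> SpectralSet:
        return sset.with_intensities(
            self.transform(sset.intensities),
            self.output_wavelengths(sset.wavelengths),
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {"method": self.method, "window": self.window, "polyorder": self.polyorder}
        if getattr(self, "reference_", None) is not None:
            d["reference"] = [float(v) for v in self.reference_]
        if hasattr(self, "n_features_in_"):
            d["n_features_in"] = int(self.n_features_in_)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralPreprocessor":
        pp = cls(method=d["method"], window=d.get("window", 11), polyorder=d.get("polyorder", 2))
        if "n_features_in" in d:
            pp.n_features_in_ = int(d["n_features_in"])
            pp.reference_ = (
                np.asarray(d["reference"], dtype=float) if "reference" in d else None
            )
        return pp
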