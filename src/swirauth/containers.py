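"""In-memory containers shared across the pipeline.

A :class:`Hypercube` is a 3-D raster ordered (line, sample, band); a
:class:`SpectralSet` is a matrix of extracted spectra (one specimen per row)
with per-row metadata carried in a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every SpectralSet carries, in canonical order
META_COLUMNS = ["specimen_id", "well_id", "half", "variety", "adulterant", "concentration_pct"]


class WavelengthGrid:
    """Strictly increasing wavelength vector in nanometres."""

    def __init__(self, values):
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid needs at least two values")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.values = values

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def stop_nm(self) -> float:
        return float(self.values[-1])

    @property
    def n_bands(self) -> int:
        return self.values.size

    @property
    def step_nm(self) -> float:
        return float((self.stop_nm - self.start_nm) / (self.n_bands - 1))

    def __len__(self) -> int:
        return self.n_bands

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"WavelengthGrid({self.start_nm:.1f}-{self.stop_nm:.1f} nm, "
            f"{self.n_bands} bands, step {self.step_nm:.2f} nm)"
        )


def as_wavelength_array(wavelengths) -> np.ndarray:
    return np.asarray(wavelengths, dtype=float)


@dataclass
class Hypercube:
    """Hyperspectral raster with axis order (line, sample, band).

    ``state`` tracks radiometric provenance: ``"raw"`` for sensor radiance,
    ``"reflectance"`` after dark/white calibration.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    state: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = as_wavelength_array(self.wavelengths)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (line, sample, band)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band axis length {self.data.shape[2]} != "
                f"wavelength count {self.wavelengths.size}"
            )
        if self.state not in ("raw", "reflectance"):
            raise ValueError(f"unknown radiometric state {self.state!r}")
        if self.state == "reflectance" and not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class ReferencePair:
    """Dark-current and white-reference cubes for reflectance calibration.

    References may have a single line (one scanned reference strip) which is
    broadcast across the target cube's lines.
    """

    dark: Hypercube
    white: Hypercube

    def __post_init__(self):
        if self.dark.n_bands != self.white.n_bands:
            raise ValueError("dark and white references disagree on band count")


@dataclass
class ForegroundMask:
    """Boolean powder/background mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class SpectralSet:
    """Matrix of specimen spectra plus aligned per-row metadata.

    ``intensities`` is (n_specimens, n_bands); ``meta`` holds the columns in
    :data:`META_COLUMNS` (specimen id, source well, half, almond variety,
    adulterant identity, adulterant concentration in percent).
    """

    intensities: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.wavelengths = as_wavelength_array(self.wavelengths)
        if self.intensities.shape[1] != self.wavelengths.size:
            raise ValueError("spectral matrix width != wavelength count")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "specimen_id": [f"s{i}" for i in range(len(self))],
                    "well_id": "",
                    "half": "all",
                    "variety": "",
                    "adulterant": "",
                    "concentration_pct": np.nan,
                }
            )
        self.meta = self.meta.reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata rows != spectra rows")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[1]

    @property
    def concentrations(self) -> np.ndarray:
        return self.meta["concentration_pct"].to_numpy(dtype=float)

    def with_intensities(self, intensities, wavelengths=None) -> "SpectralSet":
        """Copy of this set with a new spectral matrix (same metadata)."""
        return SpectralSet(
            intensities,
            self.wavelengths if wavelengths is None else wavelengths,
            self.meta.copy(),
        )

    def subset(self, row_mask) -> "SpectralSet":
        row_mask = np.asarray(row_mask)
        return SpectralSet(
            self.intensities[row_mask],
            self.wavelengths,
            self.meta.loc[row_mask].reset_index(drop=True),
        )

    def concat(self, other: "SpectralSet") -> "SpectralSet":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("cannot concatenate sets on different wavelength grids")
        return SpectralSet(
            np.vstack([self.intensities, other.intensities]),
            self.wavelengths,
            pd.concat([self.meta, other.meta], ignore_index=True),
        )
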