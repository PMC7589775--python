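"""Synthetic SWIR acquisition of powder plates.

Emulates a line-scan shortwave-infrared imager (900-2494 nm, 275 bands)
viewing a black 25-well plate of powder mixtures. Pure-component reflectance
spectra ("endmembers") are rendered as a flat baseline minus Gaussian
absorption features placed at the lipid (1165, 1395, 1692, 1734 nm), protein
(995, 1200, 1800 nm) and water (1450, 1940 nm) bands that dominate nut
powders in this range. Binary mixtures mix linearly in the mass fraction;
each pixel is then corrupted with multiplicative scatter, an additive offset,
a linear baseline tilt and white sensor noise, and mapped to radiance against
simulated dark/white reference levels so that the standard reflectance
calibration is non-trivial and exactly invertible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import Hypercube, WavelengthGrid

#: full-scale radiance fractions of the simulated references, per band
DARK_LEVEL = 0.05
WHITE_LEVEL = 0.9

#: default acquisition grid
GRID_START_NM = 900.0
GRID_STOP_NM = 2494.0
GRID_N_BANDS = 275


def make_wavelength_grid(start_nm: float, stop_nm: float, n_bands: int) -> WavelengthGrid:
    """Uniform wavelength grid; default acquisition is (900, 2494, 275)."""
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not stop_nm > start_nm:
        raise ValueError("stop_nm must exceed start_nm")
    return WavelengthGrid(np.linspace(start_nm, stop_nm, n_bands))


@dataclass(frozen=True)
class EndmemberSpec:
    """Pure-powder reflectance model: baseline minus Gaussian absorption dips.

    ``bands`` is a tuple of (center_nm, width_nm, amplitude[, variety_sign])
    features; ``variety_shift`` is the fractional amplitude perturbation a
    second cultivar of the same powder applies to its variety-sensitive
    features (those with a non-zero sign).
    """

    name: str
    bands: tuple
    baseline_level: float = 0.6
    variety_shift: float = 0.05

    def __post_init__(self):
        if not 0 < self.baseline_level < 1:
            raise ValueError("baseline_level must lie in (0, 1)")
        if self.variety_shift < 0:
            raise ValueError("variety_shift must be >= 0")
        for band in self.bands:
            center, width, amp = band[:3]
            if width <= 0 or amp < 0:
                raise ValueError("band widths must be positive, amplitudes >= 0")

    @staticmethod
    def band_variety_sign(band) -> float:
        """Per-feature sensitivity to the cultivar: amplitude scales by
        (1 + sign * variety_shift) for the second variety. Features without
        an explicit fourth element are variety-insensitive (sign 0)."""
        return float(band[3]) if len(band) > 3 else 0.0


def default_endmembers() -> dict:
    """Almond, apricot and peanut endmembers.

    Amplitudes are qualitative but ordered to match the compositional facts
    that drive the screening problem: peanut absorbs more than almond at the
    1165/1395 nm lipid-oxidation and 1200 nm protein bands, almond has the
    deepest 1734 nm long-chain fatty-acid band, and apricot (lower oil) has
    lipid bands scaled to 0.6x almond — making apricot spectrally farther
    from almond than peanut is, which reproduces the observed difficulty
    ordering (apricot easier to detect and quantify than peanut).

    The cultivar (variety) difference is carried by the O-H water bands
    (1450/1940 nm; moisture varies with origin and storage), which keeps it
    nearly orthogonal to both adulteration directions — cultivars are
    spectrally distinct, yet a concentration model calibrated on one variety
    transfers to the other with small bias, as observed.
    """
    water = ((1450.0, 60.0, 0.16, 1.0), (1940.0, 70.0, 0.25, 1.0))
    almond = EndmemberSpec(
        "almond",
        (
            (995.0, 20.0, 0.030),
            (1165.0, 25.0, 0.100),
            (1200.0, 30.0, 0.060),
            (1395.0, 30.0, 0.120),
            (1692.0, 22.0, 0.080),
            (1734.0, 22.0, 0.140),
            (1800.0, 30.0, 0.040),
        )
        + water,
    )
    peanut = EndmemberSpec(
        "peanut",
        (
            (995.0, 20.0, 0.035),
            (1165.0, 25.0, 0.120),
            (1200.0, 30.0, 0.080),
            (1395.0, 30.0, 0.140),
            (1692.0, 22.0, 0.090),
            (1734.0, 22.0, 0.120),
            (1800.0, 30.0, 0.050),
        )
        + water,
    )
    apricot = EndmemberSpec(
        "apricot",
        (
            (995.0, 20.0, 0.030),
            (1165.0, 25.0, 0.060),
            (1200.0, 30.0, 0.070),
            (1395.0, 30.0, 0.072),
            (1692.0, 22.0, 0.048),
            (1734.0, 22.0, 0.084),
            (1800.0, 30.0, 0.040),
            (1450.0, 60.0, 0.180, 1.0),
            (1940.0, 70.0, 0.270, 1.0),
        ),
    )
    return {"almond": almond, "apricot": apricot, "peanut": peanut}


def render_endmember(spec: EndmemberSpec, grid: WavelengthGrid, variety="1") -> np.ndarray:
    """Deterministic pure-component reflectance spectrum on ``grid``.

    Variety "2" perturbs each feature's amplitude by the fraction
    ``variety_shift`` times that feature's variety sign (default endmembers:
    +1 on the water bands, 0 elsewhere).
    """
    lam = np.asarray(grid, dtype=float)
    variety = str(variety)
    if variety not in ("1", "2"):
        raise ValueError(f"unknown variety {variety!r}")
    reflectance = np.full(lam.shape, spec.baseline_level)
    for band in spec.bands:
        center, width, amp = band[:3]
        if not lam[0] <= center <= lam[-1]:
            raise ValueError(f"band center {center} nm outside the wavelength grid")
        if variety == "2":
            amp = amp * (1.0 + spec.variety_shift * EndmemberSpec.band_variety_sign(band))
        reflectance -= amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
    if reflectance.min() <= 0.0 or reflectance.max() >= 1.0:
        raise ValueError("endmember amplitudes drive reflectance outside (0, 1)")
    return np.clip(reflectance, 0.01, 0.99)


def mix_spectra(pure: np.ndarray, adulterant: np.ndarray, fraction: float) -> np.ndarray:
    """Linear binary mixture: (1-f)*pure + f*adulterant."""
    pure = np.asarray(pure, dtype=float)
    adulterant = np.asarray(adulterant, dtype=float)
    if pure.shape != adulterant.shape:
        raise ValueError("component spectra must have equal length")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("mixing fraction must lie in [0, 1]")
    return (1.0 - fraction) * pure + fraction * adulterant


@dataclass(frozen=True)
class NoiseModel:
    """Per-pixel measurement corruption, all in reflectance units.

    A measured pixel spectrum is b*s + a + tilt*lam_norm + eps with
    b ~ N(1, scatter_slope_sd), a ~ N(0, scatter_offset_sd),
    tilt ~ N(0, baseline_tilt_sd) and eps ~ N(0, additive_sd) iid per band;
    lam_norm runs 0..1 over the grid. Models multiplicative light scattering,
    path-length offsets, illumination drift and sensor noise.
    """

    additive_sd: float = 0.01
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    baseline_tilt_sd: float = 0.01

    def __post_init__(self):
        for name in ("additive_sd", "scatter_slope_sd", "scatter_offset_sd", "baseline_tilt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def scaled(self, slope_factor: float = 1.0) -> "NoiseModel":
        return replace(self, scatter_slope_sd=self.scatter_slope_sd * slope_factor)


def _corrupt_matrix(spectra: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Corrupt each row of ``spectra`` independently."""
    n, j = spectra.shape
    lam_norm = np.linspace(0.0, 1.0, j)
    b = rng.normal(1.0, noise.scatter_slope_sd, size=(n, 1))
    a = rng.normal(0.0, noise.scatter_offset_sd, size=(n, 1))
    tilt = rng.normal(0.0, noise.baseline_tilt_sd, size=(n, 1))
    eps = rng.normal(0.0, noise.additive_sd, size=(n, j))
    return b * spectra + a + tilt * lam_norm + eps


def corrupt_spectrum(s: np.ndarray, noise: NoiseModel, rng_seed: int) -> np.ndarray:
    """Apply the noise model to one spectrum; reproducible per seed."""
    s = np.atleast_2d(np.asarray(s, dtype=float))
    rng = np.random.default_rng(rng_seed)
    return _corrupt_matrix(s, noise, rng)[0]


@dataclass(frozen=True)
class MixtureDesign:
    """Wells of one plate: adulterant, almond variety, concentration per well."""

    adulterant: str
    variety: str
    concentrations_pct: tuple
    replicates_per_concentration: int = 1
    seed: int = 0

    def __post_init__(self):
        for c in self.concentrations_pct:
            if not 0.0 <= c <= 100.0:
                raise ValueError("concentrations must lie in [0, 100]%")
        if self.replicates_per_concentration < 1:
            raise ValueError("replicates_per_concentration must be >= 1")

    @property
    def well_concentrations(self) -> np.ndarray:
        return np.repeat(
            np.asarray(self.concentrations_pct, dtype=float),
            self.replicates_per_concentration,
        )

    @property
    def n_wells(self) -> int:
        return self.well_concentrations.size


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of the well plate as seen by the imager, in pixels.

    Defaults place a 5x5 plate of 25 mm wells under a 324-pixel scan line
    covering roughly a quarter metre of field of view (~1.3 px/mm), i.e.
    about 800 powder pixels per well.
    """

    rows: int = 5
    cols: int = 5
    well_diameter_px: int = 32
    well_pitch_px: int = 40
    image_width_px: int = 324
    margin_px: int = 5

    def __post_init__(self):
        if self.well_diameter_px > self.well_pitch_px:
            raise ValueError("wells overlap: diameter exceeds pitch")
        if self.cols * self.well_pitch_px > self.image_width_px:
            raise ValueError("plate wider than image")

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    @property
    def image_height_px(self) -> int:
        return self.rows * self.well_pitch_px + 2 * self.margin_px

    def well_centers(self, n_wells: int) -> np.ndarray:
        """(row, col) pixel centers of the first ``n_wells`` wells, row-major."""
        if n_wells > self.capacity:
            raise ValueError(f"{n_wells} wells exceed plate capacity {self.capacity}")
        col_offset = (self.image_width_px - self.cols * self.well_pitch_px) // 2
        centers = []
        for k in range(n_wells):
            r, c = divmod(k, self.cols)
            centers.append(
                (
                    self.margin_px + r * self.well_pitch_px + self.well_pitch_px // 2,
                    col_offset + c * self.well_pitch_px + self.well_pitch_px // 2,
                )
            )
        return np.asarray(centers, dtype=int)

    def well_pixel_mask(self, n_wells: int) -> np.ndarray:
        """Ground-truth labeled image: 0 background, well k+1 on its disk."""
        labels = np.zeros((self.image_height_px, self.image_width_px), dtype=int)
        rr, cc = np.mgrid[0 : self.image_height_px, 0 : self.image_width_px]
        radius = self.well_diameter_px / 2.0
        for k, (r0, c0) in enumerate(self.well_centers(n_wells)):
            disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
            labels[disk] = k + 1
        return labels


def render_plate_cube(
    design: MixtureDesign,
    layout: PlateLayout = PlateLayout(),
    endmembers: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    grid: WavelengthGrid | None = None,
):
    """Render one plate as (raw, dark, white, truth) per the acquisition model.

    Every well pixel carries the well's mixture reflectance independently
    corrupted per pixel, mapped to radiance as dark + R*(white - dark);
    background pixels sit near the dark level. The dark and white references
    are single-line cubes (broadcast over lines at calibration time). The
    truth table lists well_id, center (row, col), concentration, adulterant
    and variety. Fully deterministic given ``design.seed``.
    """
    if endmembers is None:
        endmembers = default_endmembers()
    if grid is None:
        grid = make_wavelength_grid(GRID_START_NM, GRID_STOP_NM, GRID_N_BANDS)
    lam = np.asarray(grid, dtype=float)
    concentrations = design.well_concentrations
    n_wells = concentrations.size
    if n_wells > layout.capacity:
        raise ValueError(f"{n_wells} wells exceed plate capacity {layout.capacity}")

    pure = render_endmember(endmembers["almond"], grid, design.variety)
    adulterant_name = design.adulterant if design.adulterant in endmembers else "almond"
    adulterant = render_endmember(endmembers[adulterant_name], grid, "1")

    labels = layout.well_pixel_mask(n_wells)
    centers = layout.well_centers(n_wells)
    shape = (layout.image_height_px, layout.image_width_px, lam.size)

    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(n_wells + 1)
    bg_rng = np.random.default_rng(children[0])

    raw = np.empty(shape)
    scale = WHITE_LEVEL - DARK_LEVEL
    background = labels == 0
    raw[background] = DARK_LEVEL + bg_rng.normal(0.0, 0.002, size=(int(background.sum()), lam.size))

    rows = []
    for k in range(n_wells):
        conc = concentrations[k]
        well_px = labels == k + 1
        spectrum = mix_spectra(pure, adulterant, conc / 100.0)
        rng = np.random.default_rng(children[k + 1])
        reflectance = _corrupt_matrix(
            np.broadcast_to(spectrum, (int(well_px.sum()), lam.size)), noise, rng
        )
        raw[well_px] = DARK_LEVEL + reflectance * scale
        rows.append(
            {
                "well_id": f"w{k:02d}",
                "row": int(centers[k, 0]),
                "col": int(centers[k, 1]),
                "concentration_pct": float(conc),
                "adulterant": design.adulterant,
                "variety": str(design.variety),
            }
        )

    ref_shape = (1, layout.image_width_px, lam.size)
    dark = Hypercube(np.full(ref_shape, DARK_LEVEL), lam, state="raw")
    white = Hypercube(np.full(ref_shape, WHITE_LEVEL), lam, state="raw")
    truth = pd.DataFrame(rows)
    return Hypercube(raw, lam, state="raw"), dark, white, truth
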