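import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swirauth import (
    MixtureDesign,
    PlateLayout,
    calibrate_reflectance,
    crop_bands,
    default_endmembers,
    make_wavelength_grid,
    render_plate_cube,
    segment_background,
)
from swirauth.containers import ReferencePair

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    """The acquisition wavelength grid (900-2494 nm, 275 bands)."""
    return make_wavelength_grid(900.0, 2494.0, 275)


@pytest.fixture(scope="session")
def endmembers():
    return default_endmembers()


@pytest.fixture(scope="session")
def small_layout():
    """Compact plate geometry for fast image-pipeline tests."""
    return PlateLayout(rows=3, cols=3, well_diameter_px=12, well_pitch_px=16,
                       image_width_px=80, margin_px=4)


@pytest.fixture(scope="session")
def small_plate(small_layout):
    """One calibrated, cropped 9-well apricot plate with mask and truth."""
    design = MixtureDesign(
        adulterant="apricot",
        variety="1",
        concentrations_pct=(0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 45.0, 50.0),
        seed=11,
    )
    raw, dark, white, truth = render_plate_cube(design, small_layout)
    cube = crop_bands(calibrate_reflectance(raw, ReferencePair(dark, white)), 935, 1965)
    mask = segment_background(cube)
    return cube, mask, truth, design, small_layout


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
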