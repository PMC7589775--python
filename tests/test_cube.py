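import numpy as np
import pandas as pd
import pytest

from swirauth import (
    Hypercube,
    calibrate_reflectance,
    crop_bands,
    extract_well_spectra,
    read_envi,
    read_spectra_csv,
    segment_background,
    write_envi,
    write_spectra_csv,
)
from swirauth.containers import ForegroundMask, ReferencePair


def _cube(values, wavelengths=None, state="raw"):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(values.shape[2], dtype=float) + 1000
    return Hypercube(values, wavelengths, state=state)


class TestCalibration:
    def test_definition_values(self):
        raw = _cube(np.full((2, 2, 3), 60.0))
        refs = ReferencePair(_cube(np.full((1, 2, 3), 10.0)), _cube(np.full((1, 2, 3), 110.0)))
        cal = calibrate_reflectance(raw, refs)
        assert cal.state == "reflectance"
        assert np.allclose(cal.data, 0.5)

    def test_raw_equals_references(self):
        white = np.full((1, 2, 3), 110.0)
        dark = np.full((1, 2, 3), 10.0)
        refs = ReferencePair(_cube(dark), _cube(white))
        assert np.allclose(
            calibrate_reflectance(_cube(np.broadcast_to(white, (4, 2, 3))), refs).data, 1.0
        )
        assert np.allclose(
            calibrate_reflectance(_cube(np.broadcast_to(dark, (4, 2, 3))), refs).data, 0.0
        )

    def test_dead_reference_band_named(self):
        dark = np.full((1, 2, 3), 10.0)
        white = np.full((1, 2, 3), 110.0)
        white[..., 1] = 10.0  # dead band
        refs = ReferencePair(_cube(dark), _cube(white))
        with pytest.raises(ValueError, match="band 1"):
            calibrate_reflectance(_cube(np.full((2, 2, 3), 60.0)), refs)

    def test_per_band_gain_invariance(self, rng):
        """Scaling raw/dark/white by a common per-band gain leaves the
        reflectance unchanged."""
        raw = rng.uniform(40, 90, size=(3, 4, 5))
        dark = rng.uniform(0, 10, size=(1, 4, 5))
        white = rng.uniform(95, 120, size=(1, 4, 5))
        gain = rng.uniform(0.5, 2.0, size=5)
        a = calibrate_reflectance(_cube(raw), ReferencePair(_cube(dark), _cube(white)))
        b = calibrate_reflectance(
            _cube(raw * gain), ReferencePair(_cube(dark * gain), _cube(white * gain))
        )
        assert np.allclose(a.data, b.data)


class TestSegmentation:
    def test_two_constant_regions(self):
        img = np.full((10, 10, 2), 0.1)
        img[:, 5:] = 0.7
        mask = segment_background(_cube(img, state="reflectance"), min_component_px=1)
        assert mask.threshold == pytest.approx(0.4)
        assert mask.mask[:, 5:].all() and not mask.mask[:, :5].any()

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="single-intensity"):
            segment_background(_cube(np.full((5, 5, 2), 0.3), state="reflectance"))

    def test_plate_mask_matches_ground_truth(self, small_plate):
        cube, mask, truth, design, layout = small_plate
        labels = layout.well_pixel_mask(design.n_wells)
        truth_mask = labels > 0
        inter = np.logical_and(mask.mask, truth_mask).sum()
        union = np.logical_or(mask.mask, truth_mask).sum()
        assert inter / union >= 0.99

    def test_raw_cube_rejected(self):
        with pytest.raises(ValueError):
            segment_background(_cube(np.zeros((2, 2, 2))))


class TestCropBands:
    def test_default_grid_window(self, grid):
        lam = np.asarray(grid)
        cube = _cube(np.zeros((2, 2, lam.size)), lam, state="reflectance")
        cropped = crop_bands(cube, 935, 1965)
        oracle = int(sum(1 for w in lam if 935 <= w <= 1965))
        assert cropped.n_bands == oracle
        assert cropped.wavelengths.min() >= 935 and cropped.wavelengths.max() <= 1965

    def test_full_range_is_identity(self):
        cube = _cube(np.random.default_rng(0).random((2, 2, 5)), state="reflectance")
        out = crop_bands(cube, cube.wavelengths[0], cube.wavelengths[-1])
        assert np.array_equal(out.data, cube.data)

    def test_empty_window_rejected(self, grid):
        cube = _cube(np.zeros((1, 1, 275)), np.asarray(grid))
        with pytest.raises(ValueError):
            crop_bands(cube, 3000, 4000)
        with pytest.raises(ValueError):
            crop_bands(cube, 1965, 935)


class TestWellExtraction:
    def test_constant_well_halves_equal_the_spectrum(self):
        data = np.zeros((8, 8, 3))
        s = np.array([0.2, 0.5, 0.7])
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        data[mask] = s
        cube = _cube(data, state="reflectance")
        truth = pd.DataFrame(
            [{"well_id": "w00", "row": 3, "col": 3, "concentration_pct": 0.0,
              "adulterant": "none", "variety": "1"}]
        )
        sset = extract_well_spectra(cube, ForegroundMask(mask, 0.1), truth, halves=True)
        assert len(sset) == 2
        assert np.allclose(sset.intensities, s)

    def test_half_mean_equals_well_mean_for_equal_halves(self, rng):
        """A rectangular well with an even column count splits into two
        equal-sized halves, so the mean of the half-spectra equals the
        whole-well mean."""
        data = np.zeros((8, 8, 3))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        data[mask] = rng.uniform(0.2, 0.8, size=(16, 3))
        cube = _cube(data, state="reflectance")
        truth = pd.DataFrame(
            [{"well_id": "w00", "row": 3, "col": 3, "concentration_pct": 0.0,
              "adulterant": "none", "variety": "1"}]
        )
        fg = ForegroundMask(mask, 0.1)
        halves = extract_well_spectra(cube, fg, truth, halves=True)
        whole = extract_well_spectra(cube, fg, truth, halves=False)
        assert np.allclose(halves.intensities.mean(axis=0), whole.intensities[0],
                           atol=1e-12)

    def test_pure_plate_yields_two_spectra_per_well(self, small_plate):
        cube, mask, truth, design, _ = small_plate
        sset = extract_well_spectra(cube, mask, truth, halves=True)
        assert len(sset) == 2 * design.n_wells
        doubled = sset.concat(sset)
        assert len(doubled) == 4 * design.n_wells

    def test_commutes_with_band_cropping(self, small_plate):
        cube, mask, truth, _, _ = small_plate
        a = extract_well_spectra(crop_bands(cube, 1100, 1800), mask, truth)
        b = crop_bands(extract_well_spectra(cube, mask, truth), 1100, 1800)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.wavelengths, b.wavelengths)

    def test_tiny_well_rejected(self):
        data = np.zeros((4, 4, 2))
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        truth = pd.DataFrame(
            [{"well_id": "w00", "row": 1, "col": 1, "concentration_pct": 0.0,
              "adulterant": "none", "variety": "1"}]
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            extract_well_spectra(
                _cube(data, state="reflectance"), ForegroundMask(mask, 0.1), truth
            )


class TestRoundTrips:
    def test_envi_round_trip_bit_exact(self, tmp_path, rng):
        cube = _cube(rng.random((4, 6, 5)), state="reflectance")
        path = write_envi(cube, tmp_path / "cube.raw")
        back = read_envi(path)
        assert np.array_equal(back.data, cube.data)
        assert np.array_equal(back.wavelengths, cube.wavelengths)
        assert back.state == "reflectance"

    def test_header_band_mismatch_rejected(self, tmp_path, rng):
        cube = _cube(rng.random((2, 3, 4)), state="reflectance")
        path = write_envi(cube, tmp_path / "cube.raw")
        hdr = path.with_suffix(".hdr")
        hdr.write_text(hdr.read_text().replace("bands = 4", "bands = 5"))
        with pytest.raises(ValueError):
            read_envi(path)

    def test_missing_header_field_rejected(self, tmp_path, rng):
        cube = _cube(rng.random((2, 3, 4)))
        path = write_envi(cube, tmp_path / "cube.raw")
        hdr = path.with_suffix(".hdr")
        hdr.write_text(
            "\n".join(l for l in hdr.read_text().splitlines() if "wavelength =" not in l)
        )
        with pytest.raises(ValueError, match="wavelength"):
            read_envi(path)

    def test_spectra_csv_round_trip_bit_exact(self, tmp_path, small_plate):
        cube, mask, truth, _, _ = small_plate
        sset = extract_well_spectra(cube, mask, truth)
        path = write_spectra_csv(sset, tmp_path / "spectra.csv")
        back = read_spectra_csv(path)
        assert np.array_equal(back.intensities, sset.intensities)
        assert np.array_equal(back.wavelengths, sset.wavelengths)
        assert back.meta["specimen_id"].tolist() == sset.meta["specimen_id"].tolist()
        assert np.array_equal(back.concentrations, sset.concentrations)

    def test_csv_missing_metadata_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("specimen_id,1000.0\na,0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_spectra_csv(tmp_path / "bad.csv")
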