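"""Hypercube I/O and image-side processing.

Covers the standard imaging steps: reflectance calibration against dark and
white references, powder/background segmentation by a two-cluster intensity
threshold, cropping to the 935-1965 nm analysis window, and extraction of
averaged well spectra (each well split into two halves about its centroid
column, each half averaged to one specimen spectrum).

Cubes are stored as ENVI band-sequential rasters with an ASCII header;
spectral sets as plain CSV with one column per band.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import META_COLUMNS, ForegroundMask, Hypercube, ReferencePair, SpectralSet

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


# ---------------------------------------------------------------------------
# calibration


def calibrate_reflectance(raw: Hypercube, refs: ReferencePair) -> Hypercube:
    """Relative reflectance (raw - dark) / (white - dark), per element.

    References with a single line are broadcast over the cube's lines. A band
    where the white and dark references coincide anywhere signals a dead
    reference and raises, naming the band.
    """
    if raw.state != "raw":
        raise ValueError("cube is already calibrated")
    dark = refs.dark.data
    white = refs.white.data
    denom = white - dark
    zero_bands = np.nonzero(np.any(denom == 0, axis=tuple(range(denom.ndim - 1))))[0]
    if zero_bands.size:
        b = int(zero_bands[0])
        raise ValueError(
            f"white reference equals dark current at band {b} "
            f"({raw.wavelengths[b]:.1f} nm): dead reference"
        )
    data = (raw.data - dark) / denom
    return Hypercube(data, raw.wavelengths, state="reflectance")


# ---------------------------------------------------------------------------
# segmentation


def _two_means_threshold(values: np.ndarray) -> float:
    """Midpoint of the two cluster means of a 1-D two-means clustering.

    Lloyd iteration initialised at the data extremes; deterministic.
    """
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("single-intensity image: no background/powder contrast")
    m0, m1 = lo, hi
    for _ in range(200):
        cut = 0.5 * (m0 + m1)
        low = values[values <= cut]
        high = values[values > cut]
        if low.size == 0 or high.size == 0:
            break
        n0, n1 = float(low.mean()), float(high.mean())
        if n0 == m0 and n1 == m1:
            break
        m0, m1 = n0, n1
    return 0.5 * (m0 + m1)


def segment_background(cube: Hypercube, min_component_px: int = 10) -> ForegroundMask:
    """Threshold the mean-over-bands image at the midpoint of the two
    intensity-cluster means; pixels above the threshold are powder.

    Foreground connected components smaller than ``min_component_px`` are
    removed as specks.
    """
    if cube.state != "reflectance":
        raise ValueError("segment a calibrated (reflectance) cube")
    img = cube.data.mean(axis=2)
    threshold = _two_means_threshold(img.ravel())
    mask = img > threshold
    if min_component_px > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_component_px) + 1
        if small.size:
            mask &= ~np.isin(labels, small)
    return ForegroundMask(mask, threshold)


# ---------------------------------------------------------------------------
# band cropping


def crop_bands(obj, low_nm: float, high_nm: float):
    """Retain bands with low_nm <= wavelength <= high_nm (cube or spectra)."""
    if not low_nm < high_nm:
        raise ValueError("low_nm must be below high_nm")
    lam = np.asarray(obj.wavelengths, dtype=float)
    keep = (lam >= low_nm) & (lam <= high_nm)
    if not keep.any():
        raise ValueError(f"no bands inside [{low_nm}, {high_nm}] nm")
    if isinstance(obj, Hypercube):
        return Hypercube(obj.data[:, :, keep], lam[keep], state=obj.state)
    if isinstance(obj, SpectralSet):
        return SpectralSet(obj.intensities[:, keep], lam[keep], obj.meta.copy())
    raise TypeError(f"cannot crop {type(obj).__name__}")


# ---------------------------------------------------------------------------
# well-spectrum extraction


def _assign_wells(mask: np.ndarray, truth: pd.DataFrame) -> np.ndarray:
    """Label each foreground pixel with the nearest well (1-based index)."""
    centers = truth[["row", "col"]].to_numpy(dtype=float)
    rr, cc = np.nonzero(mask)
    d2 = (rr[:, None] - centers[None, :, 0]) ** 2 + (cc[:, None] - centers[None, :, 1]) ** 2
    nearest = d2.argmin(axis=1)
    labels = np.zeros(mask.shape, dtype=int)
    labels[rr, cc] = nearest + 1
    return labels


def extract_well_spectra(
    cube: Hypercube,
    mask: ForegroundMask,
    truth: pd.DataFrame,
    halves: bool = True,
) -> SpectralSet:
    """Average well pixels into specimen spectra.

    With ``halves`` each well's foreground pixels are split left/right about
    the well's centroid column (pixels on the centroid column go to the left
    half) and each half is averaged into one spectrum — the extraction scheme
    that doubles the specimen count per plate. Otherwise one spectrum per
    well. Labels are copied from the truth table.
    """
    if cube.state != "reflectance":
        raise ValueError("extract from a calibrated (reflectance) cube")
    if mask.mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube")
    labels = _assign_wells(mask.mask, truth)
    spectra, meta_rows = [], []
    for i, rec in truth.reset_index(drop=True).iterrows():
        well_px = labels == i + 1
        rr, cc = np.nonzero(well_px)
        if rr.size == 0:
            raise ValueError(f"well {rec['well_id']} has no foreground pixels")
        pix = cube.data[rr, cc, :]
        if halves:
            ccol = cc.mean()
            parts = (("L", cc <= ccol), ("R", cc > ccol))
        else:
            parts = (("A", np.ones(rr.size, dtype=bool)),)
        for tag, sel in parts:
            if sel.sum() < 2:
                raise ValueError(
                    f"well {rec['well_id']} half {tag}: fewer than 2 foreground pixels"
                )
            spectra.append(pix[sel].mean(axis=0))
            meta_rows.append(
                {
                    "specimen_id": f"{rec['well_id']}{tag}",
                    "well_id": rec["well_id"],
                    "half": {"L": "left", "R": "right", "A": "all"}[tag],
                    "variety": str(rec["variety"]),
                    "adulterant": rec["adulterant"],
                    "concentration_pct": float(rec["concentration_pct"]),
                }
            )
    return SpectralSet(np.vstack(spectra), cube.wavelengths, pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# ENVI band-sequential I/O


def write_envi(cube: Hypercube, path) -> Path:
    """Write an ENVI band-sequential raster plus ASCII header.

    ``path`` names the binary data file; the header is written alongside with
    a ``.hdr`` suffix. Round-trips bit-exactly for float32/float64 cubes.
    """
    path = Path(path)
    code = _ENVI_CODES.get(cube.data.dtype, 5)
    data = cube.data.astype(_ENVI_DTYPES[code], copy=False)
    hdr = path.with_suffix(".hdr")
    wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {swirauth simulated hypercube}\n"
        f"samples = {cube.n_samples}\n"
        f"lines = {cube.n_lines}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"state = {cube.state}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr.write_text(header)
    # BSQ: band-major storage
    np.ascontiguousarray(data.transpose(2, 0, 1)).tofile(path)
    return path


def _parse_envi_header(text: str) -> dict:
    fields = {}
    # join brace-delimited multi-line values
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path) -> Hypercube:
    """Read an ENVI band-sequential raster written by :func:`write_envi`."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave", "wavelength"):
        if key not in fields:
            raise ValueError(f"ENVI header missing field {key!r}")
    if fields["interleave"].lower() != "bsq":
        raise ValueError("only band-sequential (bsq) interleave is supported")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPES.get(int(fields["data type"]))
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type {fields['data type']}")
    wl = [float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()]
    if len(wl) != bands:
        raise ValueError(f"header lists {len(wl)} wavelengths for {bands} bands")
    data = np.fromfile(path, dtype=dtype)
    if data.size != samples * lines * bands:
        raise ValueError("raster size does not match header dimensions")
    cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    return Hypercube(cube.astype(dtype), wl, state=fields.get("state", "raw"))


# ---------------------------------------------------------------------------
# spectra CSV I/O


def write_spectra_csv(sset: SpectralSet, path) -> Path:
    """CSV with metadata columns then one column per band named by wavelength."""
    path = Path(path)
    band_cols = [f"{w!r}" for w in sset.wavelengths.tolist()]
    df = pd.concat(
        [
            sset.meta[META_COLUMNS].reset_index(drop=True),
            pd.DataFrame(sset.intensities, columns=band_cols),
        ],
        axis=1,
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_spectra_csv(path) -> SpectralSet:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra CSV missing columns {missing}")
    band_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not band_cols:
        raise ValueError("spectra CSV has no band columns")
    wavelengths = np.asarray([float(c) for c in band_cols])
    meta = df[META_COLUMNS].copy()
    meta["variety"] = meta["variety"].astype(str)
    return SpectralSet(df[band_cols].to_numpy(dtype=float), wavelengths, meta)
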