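"""Per-pixel adulterant-concentration mapping.

Every foreground pixel spectrum of a calibrated, band-cropped cube is passed
through the regression model's pretreatment and its affine map (beta vector
plus intercept), producing a 2-D concentration image. Background pixels are
missing (NaN under an explicit mask, never a sentinel concentration); the
rendered image clips the displayed range to the mixture-design span
(0-50% by default) on a blue-to-red scale with black background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from PIL import Image

from .containers import ForegroundMask, Hypercube
from .plsr import PLS1Regression

logger = logging.getLogger(__name__)


@dataclass
class ConcentrationMap:
    """2-D per-pixel predicted concentration (%) with background missing."""

    values: np.ndarray
    mask: ForegroundMask
    scale: tuple = (0.0, 50.0)
    model_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("value raster and mask shapes differ")
        if not self.scale[0] < self.scale[1]:
            raise ValueError("scale low must be below high")

    @property
    def n_missing_foreground(self) -> int:
        return int(np.isnan(self.values[self.mask.mask]).sum())


def map_concentration(
    cube: Hypercube,
    mask: ForegroundMask,
    model: PLS1Regression,
    scale: tuple = (0.0, 50.0),
    model_id: str = "pls1",
) -> ConcentrationMap:
    """Predicted concentration per foreground pixel.

    Pixels whose spectra are degenerate under the model's pretreatment (e.g.
    constant under SNV) are set missing, counted and logged.
    """
    if cube.state != "reflectance":
        raise ValueError("map a calibrated (reflectance) cube")
    if mask.mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube")
    values = np.full(cube.spatial_shape, np.nan)
    rr, cc = np.nonzero(mask.mask)
    if rr.size:
        pix = cube.data[rr, cc, :]
        pp = model.preprocessor_
        valid = pp.valid_rows(pix) if pp is not None else np.ones(rr.size, dtype=bool)
        n_bad = int((~valid).sum())
        if n_bad:
            logger.warning("%d foreground pixels degenerate under preprocessing", n_bad)
        if valid.any():
            values[rr[valid], cc[valid]] = model.predict(pix[valid])
    return ConcentrationMap(values, mask, scale=scale, model_id=model_id)


def summarize_wells(cmap: ConcentrationMap, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-well mean/sd/pixel-count of the non-missing mapped values."""
    centers = truth[["row", "col"]].to_numpy(dtype=float)
    rr, cc = np.nonzero(cmap.mask.mask)
    d2 = (rr[:, None] - centers[None, :, 0]) ** 2 + (cc[:, None] - centers[None, :, 1]) ** 2
    nearest = d2.argmin(axis=1)
    rows = []
    for i, rec in truth.reset_index(drop=True).iterrows():
        sel = nearest == i
        vals = cmap.values[rr[sel], cc[sel]]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"well {rec['well_id']} has no mapped pixels")
        rows.append(
            {
                "well_id": rec["well_id"],
                "concentration_pct": float(rec["concentration_pct"]),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_pixels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def render_map(cmap: ConcentrationMap, out_path) -> Path:
    """Write the map as a PNG (blue-to-red scale, black background) plus a
    JSON sidecar recording the scale and model id. Deterministic."""
    out_path = Path(out_path)
    low, high = cmap.scale
    norm = (np.clip(cmap.values, low, high) - low) / (high - low)
    colormap = matplotlib.colormaps["jet"]
    rgb = np.zeros(cmap.values.shape + (3,), dtype=np.uint8)
    valid = cmap.mask.mask & ~np.isnan(cmap.values)
    if valid.any():
        rgb[valid] = (np.asarray(colormap(norm[valid]))[:, :3] * 255).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(out_path, format="PNG")
    sidecar = out_path.with_suffix(out_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"scale_pct": [low, high], "model_id": cmap.model_id,
             "missing_foreground_pixels": cmap.n_missing_foreground},
            sort_keys=True,
        )
    )
    return out_path
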