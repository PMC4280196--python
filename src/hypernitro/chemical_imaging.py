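"""Pixel-wise chemical imaging: nitrogen distribution maps.

A fitted calibration model in its linear form, y = b0 + sum_i b_i * R(l_i),
is applied to every ROI pixel of a calibrated cube, giving a 2-D map of
predicted total nitrogen content.  Background and radiometrically invalid
pixels carry a no-data flag.  Maps are rendered with a linear colour
scale per organ (blue = low TNC, red = high), shared across all maps of
that organ so within-organ comparisons read directly off the colours.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .hypercube_io import Hypercube, invalid_pixel_mask
from .regression import PLSModel

__all__ = ["ChemicalMap", "predict_map", "render_maps"]


@dataclass
class ChemicalMap:
    """Per-pixel predicted TNC (%) with a no-data mask and colour bounds."""

    values: np.ndarray          # (rows, cols) predicted TNC %, NaN on nodata
    nodata: np.ndarray          # boolean (rows, cols)
    organ: str = "n/a"
    sample_id: str = ""
    scale_min: float | None = None
    scale_max: float | None = None

    def roi_mean(self) -> float:
        return float(np.nanmean(self.values[~self.nodata]))

    def save_text(self, path: str | os.PathLike) -> None:
        """Flat numeric raster, one row per image row; nodata as nan."""
        np.savetxt(path, np.where(self.nodata, np.nan, self.values),
                   fmt="%.6g")


def predict_map(cube: Hypercube, mask: np.ndarray, model: PLSModel,
                organ: str = "n/a", sample_id: str = "",
                clip_range: tuple[float, float] | None = None) -> ChemicalMap:
    """Apply the model's linear form to every masked pixel of a calibrated
    cube.

    Model wavelengths are matched to the nearest cube band; a wavelength
    farther than one grid step from any band is an error.  Predictions are
    not clipped unless ``clip_range`` is given.
    """
    if not cube.is_reflectance:
        raise ValueError("predict_map expects a calibrated (reflectance) cube")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")

    step = float(np.diff(cube.wavelengths).max()) if cube.n_bands > 1 else np.inf
    idx = np.array([cube.band_index(w, tol_nm=step) for w in model.wavelengths])

    sub = cube.data[:, :, idx].astype(float)          # (rows, cols, k)
    values = model.intercept + sub @ model.coefficients
    nodata = ~mask | invalid_pixel_mask(cube)
    if clip_range is not None:
        values = np.clip(values, *clip_range)
    values = np.where(nodata, np.nan, values)
    if (~nodata).sum() == 0:
        raise ValueError("no valid ROI pixel to predict")
    return ChemicalMap(values=values, nodata=nodata, organ=organ,
                       sample_id=sample_id)


def render_maps(maps: list[ChemicalMap], out_dir: str | os.PathLike,
                per_organ_scales: bool = True,
                scale_overrides: dict[str, tuple[float, float]] | None = None,
                cmap: str = "jet") -> dict:
    """Render each map as a PNG plus a text raster and a JSON legend.

    Colour bounds are the min/max predicted TNC over all maps of the same
    organ (or over every map when ``per_organ_scales`` is false), unless
    overridden per organ.  Low values render blue, high red; nodata is
    neutral grey.  Returns the legend metadata (bounds per organ, files).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not maps:
        raise ValueError("no maps to render")
    os.makedirs(out_dir, exist_ok=True)
    scale_overrides = scale_overrides or {}

    groups: dict[str, list[ChemicalMap]] = {}
    for m in maps:
        key = m.organ if per_organ_scales else "all"
        groups.setdefault(key, []).append(m)

    legend: dict = {"per_organ_scales": per_organ_scales, "organs": {},
                    "files": []}
    for key, group in groups.items():
        if key in scale_overrides:
            lo, hi = scale_overrides[key]
        else:
            lo = min(float(np.nanmin(m.values)) for m in group)
            hi = max(float(np.nanmax(m.values)) for m in group)
            if lo == hi:                     # constant map: centre it
                lo, hi = lo - 0.5, hi + 0.5
        legend["organs"][key] = {"scale_min": lo, "scale_max": hi}
        for m in group:
            m.scale_min, m.scale_max = lo, hi
            stem = m.sample_id or f"{key}-map"
            png = os.path.join(out_dir, f"{stem}.png")
            txt = os.path.join(out_dir, f"{stem}.txt")
            fig, ax = plt.subplots(figsize=(3, 3 * m.values.shape[0]
                                            / max(m.values.shape[1], 1)))
            cm = plt.get_cmap(cmap).copy()
            cm.set_bad(color="0.85")
            im = ax.imshow(np.ma.masked_invalid(m.values), cmap=cm,
                           vmin=lo, vmax=hi, interpolation="nearest")
            ax.set_axis_off()
            fig.colorbar(im, ax=ax, fraction=0.046, label="TNC (%)")
            fig.savefig(png, dpi=120, bbox_inches="tight")
            plt.close(fig)
            m.save_text(txt)
            legend["files"].append({"sample_id": m.sample_id, "organ": m.organ,
                                    "png": os.path.basename(png),
                                    "raster": os.path.basename(txt),
                                    "scale_min": lo, "scale_max": hi})
    with open(os.path.join(out_dir, "legend.json"), "w") as fh:
        json.dump(legend, fh, indent=1)
    return legend
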