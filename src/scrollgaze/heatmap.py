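"""Gaze-density heatmap overlays on the full-page image.

Corrected points are accumulated as unit masses on the image pixel grid,
smoothed with an isotropic Gaussian, peak-normalised, and alpha-composited
over the page image using a colormap. Pixels with zero density are left
untouched, so the overlay only tints where the participant actually looked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import SchemaError, ValidationError

_SOURCES = {
    "fixation": ("Corrected.Fixation.X", "Corrected.Fixation.Y"),
    "gaze": ("Corrected.Gaze.X", "Corrected.Gaze.Y"),
}


@dataclass(frozen=True)
class HeatmapSpec:
    """Rendering parameters.

    ``kernel_sigma`` is the Gaussian standard deviation in image pixels
    (50 px spans roughly a paragraph of text at typical page scale).
    ``source`` selects the coordinate pair: ``"fixation"``, ``"gaze"``, or
    ``"auto"`` (fixation preferred, gaze fallback). ``weight_column``
    optionally names a per-row weight (e.g. a duration) to use instead of
    unit masses.
    """

    kernel_sigma: float = 50.0
    colormap: str = "viridis"
    max_alpha: float = 0.6
    source: str = "auto"
    weight_column: str | None = None

    def __post_init__(self):
        if not self.kernel_sigma > 0:
            raise ValidationError(f"kernel_sigma must be > 0, got {self.kernel_sigma}")
        if not 0 < self.max_alpha <= 1:
            raise ValidationError(f"max_alpha must be in (0, 1], got {self.max_alpha}")
        if self.source not in ("auto", "fixation", "gaze"):
            raise ValidationError(f"source must be auto/fixation/gaze, got {self.source!r}")


def _as_image(image) -> Image.Image:
    if isinstance(image, (str, Path)):
        return Image.open(image).convert("RGB")
    if isinstance(image, np.ndarray):
        return Image.fromarray(image[:, :, :3].astype(np.uint8))
    return image.convert("RGB")


def _pick_columns(corrected: pd.DataFrame, source: str) -> tuple[str, str]:
    if source == "auto":
        for key in ("fixation", "gaze"):
            cols = _SOURCES[key]
            if cols[0] in corrected.columns and cols[1] in corrected.columns:
                return cols
        raise SchemaError(
            "no corrected coordinate columns found; expected "
            "Corrected.Fixation.X/Y or Corrected.Gaze.X/Y"
        )
    cols = _SOURCES[source]
    if cols[0] not in corrected.columns or cols[1] not in corrected.columns:
        raise SchemaError(f"requested source {source!r} but columns {cols} are absent")
    return cols


def density_grid(
    corrected: pd.DataFrame, width: int, height: int, spec: HeatmapSpec
) -> np.ndarray:
    """Peak-normalised smoothed density of the corrected points.

    Missing coordinates are skipped (they are a documented output state of
    the correction engine); points outside the image are ignored rather
    than clipped to the border. Returns an all-zero grid when no usable
    point exists.
    """
    cx, cy = _pick_columns(corrected, spec.source)
    x = corrected[cx].to_numpy(dtype=float)
    y = corrected[cy].to_numpy(dtype=float)
    if spec.weight_column is not None:
        w = corrected[spec.weight_column].to_numpy(dtype=float)
    else:
        w = np.ones_like(x)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(w))
    xi = np.rint(x[ok]).astype(int)
    yi = np.rint(y[ok]).astype(int)
    wv = w[ok]
    inside = (xi >= 0) & (xi < width) & (yi >= 0) & (yi < height)
    grid = np.zeros((height, width))
    np.add.at(grid, (yi[inside], xi[inside]), wv[inside])
    if grid.max() == 0:
        return grid
    grid = gaussian_filter(grid, sigma=spec.kernel_sigma)
    return grid / grid.max()


def generate_heatmap(
    corrected: pd.DataFrame, image, spec: HeatmapSpec | None = None
) -> Image.Image:
    """Overlay the gaze density of ``corrected`` on the full-page image.

    Per-pixel alpha is ``max_alpha * density`` (density peak-normalised to
    1), so the hottest spot is tinted at ``max_alpha`` and untouched pixels
    keep their exact original value. Returns a new RGB image of the same
    size; warns and returns an unchanged copy when no point is available.
    """
    spec = spec or HeatmapSpec()
    base = _as_image(image)
    width, height = base.size
    grid = density_grid(corrected, width, height, spec)
    arr = np.asarray(base, dtype=float)
    if grid.max() == 0:
        warnings.warn("no non-missing corrected points; returning the image unchanged")
        return base.copy()
    cmap = matplotlib.colormaps[spec.colormap]
    overlay = cmap(grid)[:, :, :3] * 255.0
    alpha = (spec.max_alpha * grid)[:, :, None]
    blended = arr * (1.0 - alpha) + overlay * alpha
    return Image.fromarray(np.rint(blended).astype(np.uint8))
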