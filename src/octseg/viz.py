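"""Rendering of parametric maps as color PNGs.

Maps are stored numerically as float TIFF; for visual review they are
rendered through a perceptually uniform colormap with masked cells shown
dark gray.  The colorbar strip is optional and suppressed by default
(maps are also consumed cropped, without annotation).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from matplotlib import colormaps

MASKED_GRAY = (60, 60, 60)


def write_map_tiff(raster: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(raster, dtype=np.float32))


def render_map(
    raster: np.ndarray,
    path: str | Path | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    colorbar: bool = False,
) -> np.ndarray:
    """Render a float raster (NaN = masked) to an 8-bit RGB image.

    Value range defaults to the finite 1st-99th percentiles.  With
    ``colorbar=True`` a vertical color-key strip is appended at the
    right.  Returns the uint8 array; writes PNG when ``path`` is given.
    """
    raster = np.asarray(raster, dtype=np.float64)
    finite = np.isfinite(raster)
    if not finite.any():
        rgb = np.tile(np.array(MASKED_GRAY, dtype=np.uint8), (*raster.shape, 1))
    else:
        lo = np.percentile(raster[finite], 1) if vmin is None else vmin
        hi = np.percentile(raster[finite], 99) if vmax is None else vmax
        if hi <= lo:
            hi = lo + 1.0
        norm = np.clip((raster - lo) / (hi - lo), 0, 1)
        rgba = colormaps[cmap](np.where(finite, norm, 0.0))
        rgb = (rgba[:, :, :3] * 255).astype(np.uint8)
        rgb[~finite] = MASKED_GRAY
    if colorbar:
        ramp = colormaps[cmap](np.linspace(1, 0, rgb.shape[0]))[:, :3]
        strip = np.repeat((ramp * 255).astype(np.uint8)[:, None, :], 12, axis=1)
        rgb = np.concatenate([rgb, strip], axis=1)
    if path is not None:
        iio.imwrite(Path(path), rgb)
    return rgb
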