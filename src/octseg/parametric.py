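"""Depth-resolved parametric maps of OCT B-scans.

Two physics-based contrasts are computed from a linear-intensity B-scan:

* the **optical attenuation coefficient** (OAC, ``mu_s``, mm^-1): the
  depth-resolved estimator that divides the local intensity by twice the
  axial pixel pitch times the remaining tail sum of the A-scan,

      mu_s(j) = I(j) / (2 * delta * sum_{i >= j} I(i)),

  which assumes the signal has decayed to (near) zero by the bottom of the
  scan.  The tail sum is truncated at the last pixel; no tail-correction
  term is added, so a depth-dependent positive bias of order
  ``exp(-2 mu delta (N - j))`` remains near the bottom of shallow scans.

* the **refined speckle contrast** (RSC, dimensionless): the local
  dispersion of the OAC field over a sliding window, normalised by the
  local mean.  Because it is computed on the attenuation map rather than
  on raw intensity, it is compensated for depth-dependent signal decay
  and reflects microstructural heterogeneity rather than attenuation
  artefacts.

Low-SNR pixels (below a dB floor over a noise reference) are masked and
never contribute to window statistics or downstream feature means.
Masked / undefined cells carry NaN, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BScan

DEFAULT_RSC_WINDOW = (10, 20)  # (depth px, width px)
DEFAULT_NOISE_FLOOR_DB = 15.0


@dataclass
class ParametricMaps:
    """Paired OAC / RSC rasters with validity masks, same shape as the scan.

    ``snr_mask`` is the raw intensity-over-noise-floor mask; ``valid_mask``
    additionally requires complete RSC window support, i.e. it is True
    exactly where *both* maps are defined.
    """

    scan_id: str
    oac: np.ndarray
    rsc: np.ndarray
    snr_mask: np.ndarray
    valid_mask: np.ndarray
    axial_pitch_mm: float = 0.0075

    def __post_init__(self) -> None:
        shapes = {self.oac.shape, self.rsc.shape, self.snr_mask.shape, self.valid_mask.shape}
        if len(shapes) != 1:
            raise ValueError("oac, rsc and masks must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.oac.shape


def compute_oac(scan: BScan) -> np.ndarray:
    """Depth-resolved attenuation coefficient per pixel, in mm^-1.

    Per A-scan (column), each pixel's linear intensity is divided by twice
    the axial pitch times the truncated sum of intensities from that pixel
    to the bottom of the scan.  Columns are summed bottom-up so that the
    small deep values accumulate first (better floating-point behaviour
    for strongly decaying signals).  Where the tail sum is zero the
    estimator is undefined and NaN is returned.
    """
    intensity = np.asarray(scan.intensity, dtype=np.float64)
    if np.any(intensity < 0):
        raise ValueError("negative intensity: OAC requires linear-scale input")
    tail = np.flip(np.cumsum(np.flip(intensity, axis=0), axis=0), axis=0)
    out = np.full(intensity.shape, np.nan)
    np.divide(intensity, 2.0 * scan.axial_pitch_mm * tail, out=out, where=tail > 0)
    return out


def snr_mask(
    scan: BScan,
    noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB,
    noise_reference: float | None = None,
) -> np.ndarray:
    """Boolean raster: True where 10*log10(I / I_noise) >= noise_floor_db.

    When no noise reference is supplied it is estimated as the median
    intensity of the bottom 5% of rows (at least one row) — the deepest
    part of the scan, where tissue signal has normally decayed into the
    noise floor.
    """
    intensity = np.asarray(scan.intensity, dtype=np.float64)
    if noise_reference is None:
        n_rows = max(1, int(round(0.05 * intensity.shape[0])))
        noise_reference = float(np.median(intensity[-n_rows:]))
    if noise_reference <= 0:
        raise ValueError(f"noise reference must be positive, got {noise_reference}")
    # I/I_noise >= 10^(floor/10), avoids log of zero pixels
    return intensity >= noise_reference * 10.0 ** (noise_floor_db / 10.0)


def depth_extent(mask: np.ndarray) -> np.ndarray:
    """Per-column fraction of depth with valid (True) signal."""
    mask = np.asarray(mask, dtype=bool)
    return mask.sum(axis=0) / mask.shape[0]


def _box_sum(arr: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Sliding-window sums via a zero-padded integral image.

    Returns an array of shape (H - wh + 1, W - ww + 1): the sum over every
    fully supported window position (top-left anchored).
    """
    wh, ww = window
    p = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=p[1:, 1:])
    return p[wh:, ww:] - p[:-wh, ww:] - p[wh:, :-ww] + p[:-wh, :-ww]


def compute_rsc(
    oac: np.ndarray,
    window: tuple[int, int] = DEFAULT_RSC_WINDOW,
    mask: np.ndarray | None = None,
    mode: str = "std",
    min_valid: int = 2,
) -> np.ndarray:
    """Refined speckle contrast: windowed dispersion / mean of the OAC field.

    Parameters
    ----------
    oac
        Attenuation raster (NaN where undefined).
    window
        (depth, width) sliding-window size; default 10 x 20 px.
    mask
        Optional boolean validity raster; False cells are excluded from the
        window statistics entirely (they do not contribute to mean or
        dispersion).  NaN cells in ``oac`` are always excluded.
    mode
        ``"std"`` (default): standard deviation / mean, the conventional
        speckle-contrast normalisation. ``"variance"``: variance / mean.
    min_valid
        Minimum number of contributing cells for a defined statistic.

    The window is centred on the output cell: for the even default sizes
    the window spans rows ``[r-5, r+5)`` and columns ``[c-10, c+10)``.
    Output cells are NaN where the window extends past the raster border
    (no padding is invented), where the centre cell itself is invalid, or
    where fewer than ``min_valid`` valid cells remain in the window.
    """
    if mode not in ("std", "variance"):
        raise ValueError(f"mode must be 'std' or 'variance', got {mode!r}")
    oac = np.asarray(oac, dtype=np.float64)
    wh, ww = window
    h, w = oac.shape
    if wh > h or ww > w:
        raise ValueError(f"window {window} larger than raster {oac.shape}")
    valid = np.isfinite(oac)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)

    values = np.where(valid, oac, 0.0)
    s1 = _box_sum(values, window)
    s2 = _box_sum(values * values, window)
    n = _box_sum(valid.astype(np.float64), window)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n
        var = np.maximum(s2 / n - mean * mean, 0.0)
        disp = np.sqrt(var) if mode == "std" else var
        core = np.where((n >= min_valid) & (mean > 0), disp / mean, np.nan)

    out = np.full((h, w), np.nan)
    # centre of a (wh, ww) window anchored at (i, j) is (i + wh//2, j + ww//2)
    r0, c0 = wh // 2, ww // 2
    out[r0 : r0 + core.shape[0], c0 : c0 + core.shape[1]] = core
    out[~valid] = np.nan
    return out


def rsc_support_mask(shape: tuple[int, int], window: tuple[int, int] = DEFAULT_RSC_WINDOW) -> np.ndarray:
    """True where a centred window of the given size fits inside the raster."""
    h, w = shape
    wh, ww = window
    out = np.zeros(shape, dtype=bool)
    r0, c0 = wh // 2, ww // 2
    out[r0 : r0 + (h - wh + 1), c0 : c0 + (w - ww + 1)] = True
    return out


def compute_maps(
    scan: BScan,
    noise_floor_db: float = DEFAULT_NOISE_FLOOR_DB,
    noise_reference: float | None = None,
    window: tuple[int, int] = DEFAULT_RSC_WINDOW,
    rsc_mode: str = "std",
) -> ParametricMaps:
    """Full parametric-map stack for one scan: SNR mask, OAC, RSC.

    Low-SNR pixels are masked out of the RSC window statistics; the
    returned ``valid_mask`` marks cells that clear the SNR floor *and*
    have complete RSC window support.
    """
    snr = snr_mask(scan, noise_floor_db=noise_floor_db, noise_reference=noise_reference)
    oac = compute_oac(scan)
    oac_masked = np.where(snr, oac, np.nan)
    rsc = compute_rsc(oac, window=window, mask=snr, mode=rsc_mode)
    valid = snr & rsc_support_mask(scan.shape, window) & np.isfinite(oac)
    return ParametricMaps(
        scan_id=scan.scan_id,
        oac=oac_masked,
        rsc=rsc,
        snr_mask=snr,
        valid_mask=valid,
        axial_pitch_mm=scan.axial_pitch_mm,
    )
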