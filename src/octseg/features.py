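"""Blockwise feature extraction from parametric maps.

A scan is partitioned left-to-right into non-overlapping blocks of 20
adjacent A-scans (trailing remainder columns dropped).  Each block is
summarised by the mean OAC and mean RSC over a fixed depth region of
interest (default rows [20, 40)), computed over valid cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parametric import ParametricMaps

DEFAULT_BLOCK_WIDTH = 20
DEFAULT_DEPTH_ROI = (20, 40)  # half-open [start, stop)
DEFAULT_MIN_VALID_FRACTION = 0.5


@dataclass
class FeatureBlock:
    """One block's (mean OAC, mean RSC) feature vector with optional label."""

    scan_id: str
    block_index: int
    a_scan_range: tuple[int, int]  # half-open lateral interval
    mean_oac: float
    mean_rsc: float
    label: str | None = None
    valid: bool = True

    @property
    def features(self) -> np.ndarray:
        return np.array([self.mean_oac, self.mean_rsc])


def extract_blocks(
    maps: ParametricMaps,
    labels: list[str] | np.ndarray | None = None,
    block_width: int = DEFAULT_BLOCK_WIDTH,
    depth_roi: tuple[int, int] = DEFAULT_DEPTH_ROI,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> list[FeatureBlock]:
    """Partition a scan's maps into feature blocks.

    Parameters
    ----------
    maps
        Parametric maps of one scan.
    labels
        Optional per-A-scan ground-truth classes; a block's label is the
        majority class over its columns (ties broken by first occurrence).
    block_width
        Lateral block size in A-scans; ``floor(width / block_width)``
        blocks are produced, remainder columns dropped.
    depth_roi
        Half-open depth interval ``[start, stop)`` of the averaging ROI.
    min_valid_fraction
        A block is flagged invalid (NaN features) when fewer than this
        fraction of its ROI cells clear the SNR mask, or when no finite
        OAC / RSC cells remain; invalid blocks are reported, never imputed.
    """
    if block_width < 1:
        raise ValueError("block_width must be >= 1")
    r0, r1 = depth_roi
    h, w = maps.shape
    if not (0 <= r0 < r1 <= h):
        raise ValueError(f"depth_roi {depth_roi} outside raster of {h} rows")
    if labels is not None and len(labels) != w:
        raise ValueError("labels must give one class per A-scan")

    n_blocks = w // block_width
    blocks: list[FeatureBlock] = []
    for k in range(n_blocks):
        c0, c1 = k * block_width, (k + 1) * block_width
        snr = maps.snr_mask[r0:r1, c0:c1]
        oac = maps.oac[r0:r1, c0:c1]
        rsc = maps.rsc[r0:r1, c0:c1]
        oac_ok = np.isfinite(oac) & snr
        rsc_ok = np.isfinite(rsc) & snr
        valid = (
            snr.mean() >= min_valid_fraction
            and oac_ok.any()
            and rsc_ok.any()
        )
        if valid:
            mean_oac = float(oac[oac_ok].mean())
            mean_rsc = float(rsc[rsc_ok].mean())
        else:
            mean_oac = mean_rsc = float("nan")
        label = None
        if labels is not None:
            col_labels = list(labels[c0:c1])
            uniq = list(dict.fromkeys(col_labels))  # preserves first occurrence
            label = max(uniq, key=col_labels.count)
        blocks.append(
            FeatureBlock(
                scan_id=maps.scan_id,
                block_index=k,
                a_scan_range=(c0, c1),
                mean_oac=mean_oac,
                mean_rsc=mean_rsc,
                label=label,
                valid=valid,
            )
        )
    return blocks
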