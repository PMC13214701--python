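"""Reading and writing of B-scans, sidecars, feature tables and assessments.

On-disk conventions:

* raster: single-channel 16-bit grayscale TIFF (canonical) or PNG;
  floating-point rasters as TIFF with float samples;
* sidecar: one JSON object per scan (axial pitch, intensity scale,
  noise floor, optional per-A-scan ground-truth labels);
* feature tables / assessments / manifests: plain CSV.

All in-memory intensities are **linear**; a sidecar declaring ``dB``
triggers conversion ``10**(value/10)`` at read time, before anything
else touches the raster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MIN_DEPTH_PX = 41  # deep enough for the 20-40 px ROI plus the 10 px RSC window
MIN_WIDTH_PX = 20  # at least one feature block


def db_to_linear(values: np.ndarray | float) -> np.ndarray | float:
    return 10.0 ** (np.asarray(values, dtype=np.float64) / 10.0)


def linear_to_db(values: np.ndarray | float) -> np.ndarray | float:
    values = np.asarray(values, dtype=np.float64)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(values)


@dataclass
class BScan:
    """A 2-D OCT cross-section: rows = depth (increasing away from the
    probe), columns = A-scans.  Intensity is linear and non-negative."""

    intensity: np.ndarray
    axial_pitch_mm: float = 0.0075
    scan_id: str = ""
    is_db: bool = False  # on-disk scale of the source raster

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("B-scan raster must be 2-D (depth x A-scans)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("B-scan intensity must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("B-scan intensity must be >= 0 in linear scale")
        if self.intensity.shape[0] < MIN_DEPTH_PX:
            raise ValueError(f"B-scan needs >= {MIN_DEPTH_PX} depth pixels, got {self.intensity.shape[0]}")
        if self.intensity.shape[1] < MIN_WIDTH_PX:
            raise ValueError(f"B-scan needs >= {MIN_WIDTH_PX} A-scans, got {self.intensity.shape[1]}")
        if self.axial_pitch_mm <= 0:
            raise ValueError("axial pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[1]


@dataclass
class ScanMetadata:
    """Sidecar record: geometry, intensity scale, noise floor, optional truth."""

    axial_pitch_mm: float = 0.0075
    intensity_scale: str = "linear"  # "linear" | "dB"
    noise_floor_db: float = 15.0
    noise_reference: float | None = None  # linear units; estimated if absent
    label: list[str] | None = None  # per-A-scan tissue class
    scan_truth: str | None = None  # scan-level binary truth: "WM" | "Tumor"

    def __post_init__(self) -> None:
        if self.intensity_scale not in ("linear", "dB"):
            raise ValueError(f"intensity_scale must be 'linear' or 'dB', got {self.intensity_scale!r}")
        if self.noise_floor_db < 0:
            raise ValueError("noise_floor_db must be >= 0")
        if self.axial_pitch_mm <= 0:
            raise ValueError("axial pitch must be positive")

    def to_json(self) -> str:
        d = {
            "axial_pitch_mm": self.axial_pitch_mm,
            "intensity_scale": self.intensity_scale,
            "noise_floor_db": self.noise_floor_db,
        }
        if self.noise_reference is not None:
            d["noise_reference"] = self.noise_reference
        if self.label is not None:
            d["label"] = list(self.label)
        if self.scan_truth is not None:
            d["scan_truth"] = self.scan_truth
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScanMetadata":
        return cls(**json.loads(text))


def read_bscan(path: str | Path, sidecar: str | Path) -> BScan:
    """Read a raster + JSON sidecar into a linear-intensity :class:`BScan`.

    The sidecar is mandatory: the axial pitch is required to give the
    attenuation coefficient its mm^-1 units.  dB rasters are converted to
    linear before anything downstream sees them.
    """
    path, sidecar = Path(path), Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar} (axial pitch is required)")
    meta = ScanMetadata.from_json(sidecar.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        raster = iio.imread(path)
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise ValueError(f"expected single-channel 2-D raster, got shape {raster.shape}")
    is_db = meta.intensity_scale == "dB"
    intensity = db_to_linear(raster) if is_db else raster.astype(np.float64)
    if meta.label is not None and len(meta.label) != intensity.shape[1]:
        raise ValueError("sidecar label length must equal the A-scan count")
    return BScan(
        intensity=intensity,
        axial_pitch_mm=meta.axial_pitch_mm,
        scan_id=path.stem,
        is_db=is_db,
    )


def write_bscan(
    scan: BScan,
    path: str | Path,
    metadata: ScanMetadata | None = None,
    dtype: str = "uint16",
) -> None:
    """Write a scan as TIFF (uint16 rounds and clips; float32/float64 exact
    to precision) plus, alongside, a ``.json`` sidecar."""
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.round(scan.intensity), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype in ("float32", "float64"):
        data = scan.intensity.astype(dtype)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, data)
    if metadata is None:
        metadata = ScanMetadata(axial_pitch_mm=scan.axial_pitch_mm)
    path.with_suffix(".json").write_text(metadata.to_json())


_FEATURE_COLUMNS = ["scan_id", "block_index", "mean_oac", "mean_rsc", "label"]


def write_feature_table(blocks: list, path: str | Path) -> None:
    """Blockwise feature vectors to CSV (12 significant digits, lossless
    round-trip at that precision).  An empty block list is an error."""
    if not blocks:
        raise ValueError("refusing to write an empty feature table")
    rows = [
        {
            "scan_id": b.scan_id,
            "block_index": b.block_index,
            "mean_oac": b.mean_oac,
            "mean_rsc": b.mean_rsc,
            "label": b.label if b.label is not None else "",
        }
        for b in blocks
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> list:
    from .features import FeatureBlock  # deferred: features has no dependency on io

    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    blocks = []
    for row in df.itertuples(index=False):
        label = row.label if row.label != "" else None
        blocks.append(
            FeatureBlock(
                scan_id=str(row.scan_id),
                block_index=int(row.block_index),
                a_scan_range=(int(row.block_index) * 20, int(row.block_index) * 20 + 20),
                mean_oac=float(row.mean_oac),
                mean_rsc=float(row.mean_rsc),
                label=label,
            )
        )
    return blocks


def read_assessments(path: str | Path):
    """Forced-choice reader calls from CSV into an :class:`AssessmentSet`.

    Expected columns: ``scan_id, reader_id, call, truth`` with call and
    truth in {WM, Tumor}.  The matrix must be complete (every reader rated
    every scan) and any third category is rejected — the forced-choice
    design admits no abstentions.
    """
    from .evaluate import AssessmentSet  # deferred: evaluate has no dependency on io

    df = pd.read_csv(path, dtype=str)
    required = {"scan_id", "reader_id", "call", "truth"}
    if not required.issubset(df.columns):
        raise ValueError(f"assessments CSV needs columns {sorted(required)}")
    bad = set(df["call"]) | set(df["truth"]) - {"WM", "Tumor"}
    bad -= {"WM", "Tumor"}
    if bad:
        raise ValueError(f"forced choice violated: unexpected categories {sorted(bad)}")
    if df.duplicated(["scan_id", "reader_id"]).any():
        raise ValueError("duplicate (scan, reader) assessment")
    truth_per_scan = df.groupby("scan_id")["truth"].nunique()
    if (truth_per_scan > 1).any():
        raise ValueError("conflicting ground truth for a scan")
    pivot = df.pivot(index="scan_id", columns="reader_id", values="call")
    if pivot.isna().any().any():
        raise ValueError("incomplete assessment matrix: every reader must rate every scan")
    scan_ids = list(pivot.index)
    truth_map = df.drop_duplicates("scan_id").set_index("scan_id")["truth"]
    truth = np.array([truth_map[s] == "Tumor" for s in scan_ids])
    calls = (pivot.to_numpy() == "Tumor")
    return AssessmentSet(
        scan_ids=scan_ids,
        truth=truth,
        reader_ids=[str(r) for r in pivot.columns],
        calls=calls,
    )


def write_assessments(assessments, path: str | Path) -> None:
    rows = []
    for i, scan in enumerate(assessments.scan_ids):
        for j, reader in enumerate(assessments.reader_ids):
            rows.append(
                {
                    "scan_id": scan,
                    "reader_id": reader,
                    "call": "Tumor" if assessments.calls[i, j] else "WM",
                    "truth": "Tumor" if assessments.truth[i] else "WM",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
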