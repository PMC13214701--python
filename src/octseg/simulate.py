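"""Synthetic OCT B-scans, tissue layouts, reader panels and archetype maps.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without any acquired data:

* per-tissue exponential depth decay (Beer-Lambert, single scattering)
  with class-specific attenuation ``mu_s``;
* fully developed speckle — unit-mean exponential intensity statistics
  (coefficient of variation 1);
* class-specific microstructural texture: a per-pixel lognormal
  reflectivity field, white in depth and laterally smoothed at a 3-column
  correlation length.  Depth variation of the texture is what raises the
  speckle contrast of heterogeneous tissue; a field constant along depth
  would cancel exactly in the per-A-scan attenuation ratio;
* an additive exponential noise floor;
* 256-pixel-deep scans of a few hundred A-scans, both homogeneous and
  heterogeneous (contiguous tumor infiltration, scattered isolated
  false-positive-like singletons).

Default tissue parameters are generator constants chosen to make the
three classes separable but overlapping; they are not measured tissue
values.  Every generator is seed-deterministic and emits ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .classify import SegmentationMap
from .evaluate import AssessmentSet
from .io import BScan, ScanMetadata, write_bscan

DEFAULT_DEPTH = 256
DEFAULT_WIDTH = 400
DEFAULT_PITCH_MM = 0.0075
LATERAL_TEXTURE_CORRELATION = 3.0  # columns


@dataclass
class TissueModel:
    """Per-class optical parameters of the three tissue types."""

    mu_s: dict[str, float] = field(
        default_factory=lambda: {"Normal": 1.0, "DamagedMatter": 2.0, "Tumor": 3.5}
    )
    sigma_tex: dict[str, float] = field(
        default_factory=lambda: {"Normal": 0.10, "DamagedMatter": 0.30, "Tumor": 0.55}
    )
    surface_intensity: float = 1.0e4
    noise_level: float = 1.0  # linear units; the additive noise floor scale

    def __post_init__(self) -> None:
        for c, m in self.mu_s.items():
            if m <= 0:
                raise ValueError(f"mu_s[{c!r}] must be > 0")
        for c, s in self.sigma_tex.items():
            if s < 0:
                raise ValueError(f"sigma_tex[{c!r}] must be >= 0")
        if len({(self.mu_s[c], self.sigma_tex[c]) for c in self.mu_s}) != len(self.mu_s):
            raise ValueError("tissue classes must have distinct parameter pairs")


@dataclass
class ScanLayout:
    """Per-A-scan true class sequence with its pattern family."""

    classes: np.ndarray  # (width,) of class names
    pattern: str = "homogeneous"

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)

    @property
    def width(self) -> int:
        return self.classes.size

    @property
    def scan_truth(self) -> str:
        return "Tumor" if np.any(self.classes == "Tumor") else "WM"

    @classmethod
    def homogeneous(cls, tissue_class: str, width: int = DEFAULT_WIDTH) -> "ScanLayout":
        return cls(classes=np.full(width, tissue_class, dtype=object), pattern="homogeneous")

    @classmethod
    def infiltration(
        cls,
        width: int = DEFAULT_WIDTH,
        start: int = 0,
        length: int = 100,
        background: str = "Normal",
        tumor_class: str = "Tumor",
    ) -> "ScanLayout":
        """A single contiguous tumor segment inside background tissue."""
        if not (0 <= start and start + length <= width and length >= 1):
            raise ValueError("infiltration segment must lie inside the scan")
        classes = np.full(width, background, dtype=object)
        classes[start : start + length] = tumor_class
        return cls(classes=classes, pattern="infiltration")

    @classmethod
    def scattered(
        cls,
        width: int = DEFAULT_WIDTH,
        positions: list[int] | None = None,
        background: str = "Normal",
    ) -> "ScanLayout":
        """Isolated non-adjacent single tumor-labeled columns."""
        classes = np.full(width, background, dtype=object)
        positions = sorted(positions or [])
        for a, b in zip(positions, positions[1:]):
            if b - a < 2:
                raise ValueError("scattered singletons must be non-adjacent")
        for p in positions:
            classes[p] = "Tumor"
        return cls(classes=classes, pattern="scattered_fp")


def _lateral_texture(
    shape: tuple[int, int],
    sigma_per_column: np.ndarray,
    rng: np.random.Generator,
    correlation: float = LATERAL_TEXTURE_CORRELATION,
) -> np.ndarray:
    """Unit-mean lognormal reflectivity field, white in depth, smoothed
    laterally to the given correlation length (in columns)."""
    g = rng.standard_normal(shape)
    g = gaussian_filter1d(g, sigma=correlation, axis=1, mode="nearest")
    # restore unit variance: smoothing white noise with kernel k leaves std ||k||_2
    impulse = np.zeros(shape[1])
    impulse[shape[1] // 2] = 1.0
    kernel_norm = np.linalg.norm(gaussian_filter1d(impulse, sigma=correlation, mode="nearest"))
    g /= kernel_norm
    s = sigma_per_column[None, :]
    return np.exp(s * g - 0.5 * s * s)


def simulate_bscan(
    layout: ScanLayout,
    tissue: TissueModel | None = None,
    depth: int = DEFAULT_DEPTH,
    axial_pitch_mm: float = DEFAULT_PITCH_MM,
    seed: int | np.random.Generator = 0,
    speckle: bool = True,
    texture: bool = True,
    noise: bool = True,
    scan_id: str = "sim",
) -> tuple[BScan, ScanMetadata]:
    """Simulate one B-scan from a layout and tissue model.

    Mean intensity per pixel is ``I0 * T * exp(-2 mu_s delta j)`` with j
    the depth row; the realised intensity multiplies in a unit-mean
    exponential speckle deviate and adds an exponential noise floor.
    With ``speckle``, ``texture`` and ``noise`` all off the scan is an
    exact noiseless exponential phantom.
    """
    tissue = tissue or TissueModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.array([tissue.mu_s[c] for c in layout.classes])
    sig = np.array([tissue.sigma_tex[c] for c in layout.classes])
    rows = np.arange(depth)[:, None]
    mean = tissue.surface_intensity * np.exp(-2.0 * mu[None, :] * axial_pitch_mm * rows)
    if texture:
        mean = mean * _lateral_texture((depth, layout.width), sig, rng)
    intensity = mean * rng.exponential(1.0, mean.shape) if speckle else mean
    if noise:
        intensity = intensity + tissue.noise_level * rng.exponential(1.0, mean.shape)
    scan = BScan(intensity=intensity, axial_pitch_mm=axial_pitch_mm, scan_id=scan_id)
    meta = ScanMetadata(
        axial_pitch_mm=axial_pitch_mm,
        intensity_scale="linear",
        noise_reference=tissue.noise_level if noise else None,
        label=list(layout.classes),
        scan_truth=layout.scan_truth,
    )
    return scan, meta


def simulate_training_cohort(
    n_scans: int = 23,
    width: int = DEFAULT_WIDTH,
    depth: int = DEFAULT_DEPTH,
    tissue: TissueModel | None = None,
    seed: int = 0,
) -> list[tuple[BScan, ScanMetadata]]:
    """Strictly homogeneous labeled scans for classifier training, cycling
    through the three classes (23 scans -> 8 Normal, 8 DamagedMatter,
    7 Tumor)."""
    tissue = tissue or TissueModel()
    rng = np.random.default_rng(seed)
    classes = ("Normal", "DamagedMatter", "Tumor")
    out = []
    for i in range(n_scans):
        layout = ScanLayout.homogeneous(classes[i % 3], width=width)
        scan, meta = simulate_bscan(
            layout, tissue, depth=depth, seed=rng, scan_id=f"train_{i:03d}"
        )
        out.append((scan, meta))
    return out


def simulate_cohort(
    n_scans: int = 86,
    class_mix: dict[str, int] | None = None,
    pattern_mix: dict[str, float] | None = None,
    tissue: TissueModel | None = None,
    seed: int = 0,
    width: int = DEFAULT_WIDTH,
    depth: int = DEFAULT_DEPTH,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[BScan, ScanMetadata]], pd.DataFrame]:
    """Reproducible evaluation cohort with per-scan truth.

    ``class_mix`` gives scan-level truth counts (default 44 WM / 42
    tumor); ``pattern_mix`` the pattern-family proportions among tumor
    scans (default half homogeneous, half contiguous infiltration).  When
    ``out_dir`` is given the scans are written as TIFF + JSON sidecars
    with a ``manifest.csv``.
    """
    class_mix = class_mix or {"WM": 44, "Tumor": 42}
    pattern_mix = pattern_mix or {"homogeneous": 0.5, "infiltration": 0.5}
    if sum(class_mix.values()) != n_scans:
        raise ValueError("class_mix counts must sum to n_scans")
    if abs(sum(pattern_mix.values()) - 1.0) > 1e-9:
        raise ValueError("pattern_mix must sum to 1")
    tissue = tissue or TissueModel()
    rng = np.random.default_rng(seed)

    layouts: list[ScanLayout] = []
    for _ in range(class_mix.get("WM", 0)):
        wm_class = "Normal" if rng.random() < 0.7 else "DamagedMatter"
        layouts.append(ScanLayout.homogeneous(wm_class, width=width))
    n_tumor = class_mix.get("Tumor", 0)
    n_infil = int(round(pattern_mix.get("infiltration", 0.0) * n_tumor))
    for i in range(n_tumor):
        if i < n_infil:
            length = int(rng.integers(width // 4, 3 * width // 4))
            start = int(rng.integers(0, width - length + 1))
            layouts.append(ScanLayout.infiltration(width=width, start=start, length=length))
        else:
            layouts.append(ScanLayout.homogeneous("Tumor", width=width))
    order = rng.permutation(len(layouts))

    cohort, rows = [], []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for new_idx, li in enumerate(order):
        layout = layouts[li]
        scan_id = f"scan_{new_idx:03d}"
        scan, meta = simulate_bscan(layout, tissue, depth=depth, seed=rng, scan_id=scan_id)
        cohort.append((scan, meta))
        row = {"scan_id": scan_id, "truth": layout.scan_truth, "pattern": layout.pattern}
        if out_dir is not None:
            raster = out_dir / f"{scan_id}.tiff"
            write_bscan(scan, raster, metadata=meta, dtype="float32")
            row["raster"] = raster.name
            row["sidecar"] = raster.with_suffix(".json").name
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return cohort, manifest


@dataclass
class ReaderModel:
    """Scan-level binary reader with fixed sensitivity/specificity."""

    reader_id: str
    sensitivity: float = 0.9
    specificity: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("reader rates must be in [0, 1]")


def simulate_reader_panel(
    truths: np.ndarray | list[bool],
    readers: list[ReaderModel],
    seed: int = 0,
    scan_ids: list[str] | None = None,
) -> AssessmentSet:
    """Draw each reader's forced-choice call per scan from their rates."""
    if not readers:
        raise ValueError("need >= 1 reader")
    truth = np.asarray(truths, dtype=bool)
    rng = np.random.default_rng(seed)
    calls = np.zeros((truth.size, len(readers)), dtype=bool)
    for j, r in enumerate(readers):
        u = rng.random(truth.size)
        calls[:, j] = np.where(truth, u < r.sensitivity, u >= r.specificity)
    if scan_ids is None:
        scan_ids = [f"scan_{i:03d}" for i in range(truth.size)]
    return AssessmentSet(
        scan_ids=scan_ids,
        truth=truth,
        reader_ids=[r.reader_id for r in readers],
        calls=calls,
    )


# --- archetype segmentation maps for the contextual-filter scenarios -------


def scattered_fp_segmap(
    scan_id: str,
    n_blocks: int = 20,
    n_singles: int = 2,
    rng: np.random.Generator | int = 0,
) -> SegmentationMap:
    """Tumor-free scan whose map carries isolated single Red blocks, each
    flanked by Green — the scattered false-positive family."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels: list[str | None] = ["Normal"] * n_blocks
    placed: list[int] = []
    while len(placed) < n_singles:
        p = int(rng.integers(1, n_blocks - 1))
        if all(abs(p - q) >= 2 for q in placed):
            placed.append(p)
    for p in placed:
        labels[p] = "Tumor"
    return SegmentationMap(
        scan_id=scan_id, labels=labels, depth_extents=np.ones(n_blocks), truth="WM"
    )


def clustered_fp_segmap(
    scan_id: str,
    n_blocks: int = 20,
    run_length: int | None = None,
    rng: np.random.Generator | int = 0,
) -> SegmentationMap:
    """Tumor-free scan whose map carries one contiguous Red cluster — the
    morphologically plausible false-positive family."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if run_length is None:
        run_length = int(rng.integers(5, 8))
    start = int(rng.integers(0, n_blocks - run_length + 1))
    labels: list[str | None] = ["Normal"] * n_blocks
    labels[start : start + run_length] = ["Tumor"] * run_length
    return SegmentationMap(
        scan_id=scan_id, labels=labels, depth_extents=np.ones(n_blocks), truth="WM"
    )


def infiltration_segmap(
    scan_id: str,
    n_blocks: int = 20,
    run_length: int | None = None,
    yellow_flank: bool = True,
    rng: np.random.Generator | int = 0,
) -> SegmentationMap:
    """True-tumor scan: a dense contiguous Red run, optionally flanked by
    Yellow (damaged-tissue transition zone)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if run_length is None:
        run_length = int(rng.integers(6, 11))
    start = int(rng.integers(1, n_blocks - run_length))
    labels: list[str | None] = ["Normal"] * n_blocks
    labels[start : start + run_length] = ["Tumor"] * run_length
    if yellow_flank:
        labels[start - 1] = "DamagedMatter"
        if start + run_length < n_blocks:
            labels[start + run_length] = "DamagedMatter"
    return SegmentationMap(
        scan_id=scan_id, labels=labels, depth_extents=np.ones(n_blocks), truth="Tumor"
    )


def archetype_cohort(
    n_scattered: int = 9,
    n_clustered: int = 4,
    n_tumor: int = 0,
    n_clean: int = 0,
    n_blocks: int = 20,
    seed: int = 0,
) -> list[SegmentationMap]:
    """Cohort of archetype segmentation maps for the override analysis:
    scattered and clustered false-positive scans, optional true-tumor
    infiltration scans and clean all-Green scans."""
    rng = np.random.default_rng(seed)
    maps = []
    for i in range(n_scattered):
        maps.append(scattered_fp_segmap(f"fp_scattered_{i:02d}", n_blocks, rng=rng))
    for i in range(n_clustered):
        maps.append(clustered_fp_segmap(f"fp_clustered_{i:02d}", n_blocks, rng=rng))
    for i in range(n_tumor):
        maps.append(infiltration_segmap(f"tumor_{i:02d}", n_blocks, rng=rng))
    for i in range(n_clean):
        maps.append(
            SegmentationMap(
                scan_id=f"clean_{i:02d}",
                labels=["Normal"] * n_blocks,
                depth_extents=np.ones(n_blocks),
                truth="WM",
            )
        )
    return maps
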