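"""Linear one-vs-rest SVM tissue classification over (OAC, RSC) features.

Three tissue classes are distinguished — normal white matter, damaged
white matter, and tumor — rendered green / yellow / red.  Features are
standardised to zero mean and unit variance before fitting; one linear
margin classifier is fit per class against the rest.  Cross-validation
is leave-one-group-out with scaling and fitting strictly contained in
each fold (default grouping: per scan, to prevent within-scan leakage).

The trained model is a plain JSON-serialisable record (scaler statistics,
per-class weights and intercepts); prediction is an explicit
``argmax_k (w_k . z + b_k)`` on standardised features, with exact ties
broken by the fixed class order Normal < DamagedMatter < Tumor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import DEFAULT_BLOCK_WIDTH, DEFAULT_DEPTH_ROI, FeatureBlock, extract_blocks
from .parametric import ParametricMaps, depth_extent

CLASSES = ("Normal", "DamagedMatter", "Tumor")
CLASS_COLORS = {"Normal": (0, 170, 0), "DamagedMatter": (230, 200, 0), "Tumor": (220, 30, 30)}
MISSING_COLOR = (128, 128, 128)
POSITIVE_CLASS = "Tumor"  # binary collapse: Tumor vs {Normal, DamagedMatter}
FEATURE_NAMES = ("mean_oac", "mean_rsc")


@dataclass
class TrainedModel:
    """Standard scaler + per-class linear decision functions.

    Decision scores for feature row ``x`` are
    ``(x - scaler_mean) / scaler_scale @ coef.T + intercept``; the
    predicted class is the argmax over the rows of ``coef`` (one per
    entry of ``classes``, in fixed order).
    """

    classes: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray  # (n_classes, 2)
    intercept: np.ndarray  # (n_classes,)
    C: float = 1.0
    training_scan_ids: tuple[str, ...] = ()
    model_id: str = "svm-ovr-linear"

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.coef.shape[1]:
            raise ValueError(f"expected {self.coef.shape[1]} features, got {X.shape[1]}")
        z = (X - self.scaler_mean) / self.scaler_scale
        return z @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> list[str]:
        scores = self.decision_function(X)
        return [self.classes[i] for i in np.argmax(scores, axis=1)]  # argmax: first max wins → fixed class-order tie-break

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "classes": list(self.classes),
                "scaler_mean": self.scaler_mean.tolist(),
                "scaler_scale": self.scaler_scale.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept.tolist(),
                "C": self.C,
                "training_scan_ids": list(self.training_scan_ids),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            coef=np.array(d["coef"]),
            intercept=np.array(d["intercept"]),
            C=d["C"],
            training_scan_ids=tuple(d["training_scan_ids"]),
            model_id=d.get("model_id", "svm-ovr-linear"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def _features_and_labels(blocks: list[FeatureBlock]) -> tuple[np.ndarray, np.ndarray]:
    usable = [b for b in blocks if b.valid and b.label is not None]
    if not usable:
        raise ValueError("no valid labeled blocks")
    X = np.array([[b.mean_oac, b.mean_rsc] for b in usable])
    y = np.array([b.label for b in usable])
    return X, y


def train(blocks: list[FeatureBlock], C: float = 1.0, tol: float = 1e-3) -> TrainedModel:
    """Fit the standardised linear OvR SVM on labeled feature blocks.

    Requires at least two classes with >= 2 blocks each; a zero-variance
    feature is refused by name (it cannot be standardised).  ``tol`` is
    the solver stopping tolerance; the default is plenty for prediction,
    tighten it when comparing decision boundaries numerically.
    """
    X, y = _features_and_labels(blocks)
    present = [c for c in CLASSES if c in y]
    unknown = set(y) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown tissue classes {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training requires >= 2 tissue classes")
    for c in present:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 blocks")
    variances = X.var(axis=0)
    for name, v in zip(FEATURE_NAMES, variances):
        if v == 0:
            raise ValueError(f"feature {name!r} has zero variance across the training blocks")

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    coef = np.zeros((len(present), 2))
    intercept = np.zeros(len(present))
    for i, c in enumerate(present):  # explicit one-vs-rest: one binary linear SVM per class
        clf = SVC(kernel="linear", C=C, tol=tol).fit(Z, y == c)
        coef[i] = clf.coef_[0]
        intercept[i] = clf.intercept_[0]
    scan_ids = tuple(dict.fromkeys(b.scan_id for b in blocks if b.valid and b.label is not None))
    return TrainedModel(
        classes=tuple(present),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=coef,
        intercept=intercept,
        C=C,
        training_scan_ids=scan_ids,
    )


@dataclass
class LoocvResult:
    """Out-of-fold predictions aligned to the input blocks."""

    blocks: list[FeatureBlock]
    classes: tuple[str, ...]
    predicted: list[str]
    scores: np.ndarray  # (n_blocks, n_classes)
    groups: list[str]
    fold_models: list[TrainedModel] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.blocks])

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.labels == np.array(self.predicted)))


def loocv(
    blocks: list[FeatureBlock],
    C: float = 1.0,
    grouping: str = "per_scan",
    keep_fold_models: bool = False,
) -> LoocvResult:
    """Leave-one-group-out cross-validation with fold-contained scaling.

    ``grouping="per_scan"`` (default) holds out all blocks of one scan per
    fold; ``"per_block"`` is classical leave-one-out over blocks.  Scaler
    and SVM are refit from scratch on each fold's training remainder; a
    fold whose remainder loses a class is an error (silent degeneracy is
    refused).
    """
    if grouping not in ("per_scan", "per_block"):
        raise ValueError(f"grouping must be 'per_scan' or 'per_block', got {grouping!r}")
    usable = [b for b in blocks if b.valid and b.label is not None]
    if grouping == "per_scan":
        groups = [b.scan_id for b in usable]
    else:
        groups = [f"{b.scan_id}:{b.block_index}" for b in usable]
    unique_groups = list(dict.fromkeys(groups))
    if len(unique_groups) < 3:
        raise ValueError("LOOCV needs >= 3 groups")
    all_classes = {b.label for b in usable}

    group_arr = np.array(groups)
    predicted: list[str | None] = [None] * len(usable)
    scores = np.full((len(usable), len(CLASSES)), np.nan)
    present_order = [c for c in CLASSES if c in all_classes]
    fold_models = []
    for g in unique_groups:
        held = group_arr == g
        train_blocks = [b for b, h in zip(usable, held) if not h]
        remainder_classes = {b.label for b in train_blocks}
        if remainder_classes != all_classes:
            lost = sorted(all_classes - remainder_classes)
            raise ValueError(f"fold {g!r} loses class(es) {lost} from its training remainder")
        model = train(train_blocks, C=C)
        if keep_fold_models:
            fold_models.append(model)
        X_held = np.array([[b.mean_oac, b.mean_rsc] for b, h in zip(usable, held) if h])
        s = model.decision_function(X_held)
        preds = model.predict(X_held)
        idx = np.flatnonzero(held)
        for row, i in enumerate(idx):
            predicted[i] = preds[row]
            for j, c in enumerate(model.classes):
                scores[i, CLASSES.index(c)] = s[row, j]
    score_cols = [CLASSES.index(c) for c in present_order]
    return LoocvResult(
        blocks=usable,
        classes=tuple(present_order),
        predicted=list(predicted),
        scores=scores[:, score_cols],
        groups=groups,
        fold_models=fold_models,
    )


def multiclass_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    classes: tuple[str, ...] = CLASSES,
) -> dict[str, dict]:
    """One-vs-rest ROC curve and trapezoidal AUC per class, plus the binary
    tumor-vs-rest task scored by the Tumor class's decision value.

    Ties are handled by sweeping thresholds over the unique score values
    (each distinct score is one operating point), which makes the AUC
    equal to the concordant-pair (Mann-Whitney) statistic with half
    credit for ties.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("ROC undefined: labels contain a single class")
    out: dict[str, dict] = {}
    for j, c in enumerate(classes):
        y = labels == c
        if y.all() or not y.any():
            continue
        fpr, tpr, thresholds = _roc_curve(y, scores[:, j])
        out[c] = {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(_trapezoid_auc(fpr, tpr))}
    if POSITIVE_CLASS in classes and POSITIVE_CLASS in out:
        out["tumor_vs_rest"] = dict(out[POSITIVE_CLASS])
    return out


@dataclass
class SegmentationMap:
    """Per-block tissue labels for one scan, with decision scores and the
    per-block valid-signal depth extent (fraction of scan depth, from the
    SNR mask) used by the contextual filter."""

    scan_id: str
    labels: list[str | None]  # None = invalid block (no features)
    scores: np.ndarray | None = None  # (n_blocks, n_classes) or None
    classes: tuple[str, ...] = CLASSES
    block_width: int = DEFAULT_BLOCK_WIDTH
    depth_extents: np.ndarray | None = None  # per block, in [0, 1]
    truth: str | None = None  # optional scan-level binary truth "WM"/"Tumor"
    model_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("empty segmentation map")
        for lab in self.labels:
            if lab is not None and lab not in self.classes:
                raise ValueError(f"unknown label {lab!r}")

    @property
    def n_blocks(self) -> int:
        return len(self.labels)


def segment(
    maps: ParametricMaps,
    model: TrainedModel,
    block_width: int = DEFAULT_BLOCK_WIDTH,
    depth_roi: tuple[int, int] = DEFAULT_DEPTH_ROI,
    truth: str | None = None,
) -> SegmentationMap:
    """Classify a scan's blocks with a trained model.

    Invalid blocks (insufficient valid signal in the ROI) are labeled
    ``None`` — missing, never imputed.
    """
    blocks = extract_blocks(maps, block_width=block_width, depth_roi=depth_roi)
    col_extent = depth_extent(maps.snr_mask)
    labels: list[str | None] = []
    extents = np.zeros(len(blocks))
    scores = np.full((len(blocks), len(model.classes)), np.nan)
    for k, b in enumerate(blocks):
        c0, c1 = b.a_scan_range
        extents[k] = float(col_extent[c0:c1].mean())
        if not b.valid:
            labels.append(None)
            continue
        s = model.decision_function(b.features[None, :])
        scores[k] = s[0]
        labels.append(model.predict(b.features[None, :])[0])
    return SegmentationMap(
        scan_id=maps.scan_id,
        labels=labels,
        scores=scores,
        classes=model.classes,
        block_width=block_width,
        depth_extents=extents,
        truth=truth,
        model_id=model.model_id,
    )


def render_segmentation(
    segmap: SegmentationMap,
    scan,
    path: str | Path | None = None,
    alpha: float = 0.45,
    legend: bool = False,
) -> np.ndarray:
    """Render block labels as green/yellow/red column stripes tinted over
    the structural image (log-compressed).  Missing blocks render neutral
    gray.  ``legend=True`` appends a small color-key strip at the right
    (suppressed by default, matching maps delivered without colorbars).
    Returns the uint8 RGB array; writes a PNG when ``path`` is given.
    """
    import imageio.v3 as iio

    intensity = np.asarray(scan.intensity, dtype=np.float64)
    log_img = np.log10(intensity + 1.0)
    rng = np.ptp(log_img)
    norm = (log_img - log_img.min()) / (rng if rng > 0 else 1.0)
    rgb = np.repeat((norm * 255).astype(np.uint8)[:, :, None], 3, axis=2).astype(np.float64)
    for k, lab in enumerate(segmap.labels):
        c0 = k * segmap.block_width
        c1 = min(c0 + segmap.block_width, rgb.shape[1])
        color = np.array(CLASS_COLORS.get(lab, MISSING_COLOR), dtype=np.float64)
        rgb[:, c0:c1, :] = (1 - alpha) * rgb[:, c0:c1, :] + alpha * color
    out = np.clip(rgb, 0, 255).astype(np.uint8)
    if legend:
        strip = np.zeros((out.shape[0], 12, 3), dtype=np.uint8)
        h = out.shape[0] // 3
        for i, c in enumerate(CLASSES):
            strip[i * h : (i + 1) * h, :, :] = CLASS_COLORS[c]
        out = np.concatenate([out, strip], axis=1)
    if path is not None:
        iio.imwrite(Path(path), out)
    return out
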