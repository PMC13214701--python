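"""Contextual override filter: a deterministic model of the human review step.

Blockwise tissue segmentation of OCT scans produces sporadic Tumor (Red)
false positives.  A reviewing clinician does not take each Red stripe at
face value: isolated Red stripes surrounded by Normal (Green) tissue are
biologically implausible and get dismissed as noise, dense contiguous Red
clusters — especially adjoining Damaged (Yellow) tissue — are taken
seriously, and evidence confined to a shallow sliver of the scan is
discounted.  This module encodes those heuristics as an explicit,
reproducible rule engine that turns a per-block segmentation map into a
scan-level tumor probability and a binary call.

It is a model of the contextual review step, not a claim about surgeon
cognition; every quantification of the qualitative rules (run length,
density thresholds, neighbour weight, depth fraction) is a configurable
engineering default.

Scoring recipe (all steps monotone in the Red evidence):

1. *Suppression*: maximal Red runs shorter than ``min_run`` whose existing
   neighbours are all Green are removed (the scattered-false-positive
   rule).  A run touching the scan edge is judged on its single inner
   neighbour.
2. *Density*: the surviving Red fraction f maps to a base score — 0.1 for
   f <= low, 0.9 for f >= high, linear in between.
3. *Neighbourhood*: if any surviving Red block adjoins a Yellow block the
   evidence is amplified by ``neighbor_weight``.
4. *Depth*: the evidence is attenuated by ``min(1, extent/depth_fraction)``
   where extent is the deepest valid-signal fraction among surviving Red
   blocks (shallow evidence is discounted).

The amplification/attenuation act on the evidence above the no-evidence
baseline: p = clip(0.1 + (base - 0.1) * amp * depth_factor, 0, 1).  This
anchoring keeps the score monotone — adding a Red block can never lower
the probability — which a bare product of factors would violate for
shallow evidence.  The binary call is Tumor iff p strictly exceeds the
decision threshold (a probability of exactly 0.5 is called WM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import SegmentationMap

BASE_LOW = 0.1  # score assigned when the surviving Red fraction is <= density_low
BASE_HIGH = 0.9  # score assigned when it is >= density_high


@dataclass
class FilterConfig:
    """Tunable quantification of the qualitative review rules."""

    min_run: int = 2
    density_low: float = 0.10
    density_high: float = 0.30
    neighbor_weight: float = 1.5
    depth_fraction: float = 0.5
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 <= self.density_low < self.density_high:
            raise ValueError("need 0 <= density_low < density_high")
        if self.neighbor_weight < 1:
            raise ValueError("neighbor_weight must be >= 1")
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must be in (0, 1]")
        if not 0 <= self.decision_threshold <= 1:
            raise ValueError("decision_threshold must be in [0, 1]")


@dataclass
class ScanVerdict:
    """Scan-level outcome with a reproducible evidence trace."""

    scan_id: str
    tumor_probability: float
    call: str  # "WM" | "Tumor"
    evidence: dict = field(default_factory=dict)


def _red_runs(labels: list[str | None]) -> list[tuple[int, int]]:
    """Maximal runs of Tumor blocks as half-open [start, stop) intervals."""
    runs = []
    start = None
    for i, lab in enumerate(labels + [None]):
        if lab == "Tumor" and start is None:
            start = i
        elif lab != "Tumor" and start is not None:
            runs.append((start, i))
            start = None
    return runs


def score_scan(
    segmap: SegmentationMap,
    depth_evidence: np.ndarray | None = None,
    cfg: FilterConfig | None = None,
) -> ScanVerdict:
    """Apply the contextual rules to one segmentation map.

    ``depth_evidence`` gives each block's valid-signal depth extent in
    [0, 1]; when omitted it is taken from the map itself
    (``segmap.depth_extents``) and defaults to full depth.
    """
    cfg = cfg or FilterConfig()
    labels = segmap.labels
    n = len(labels)
    if n == 0:
        raise ValueError("empty segmentation map")
    if depth_evidence is None:
        depth_evidence = segmap.depth_extents
    if depth_evidence is None:
        depth_evidence = np.ones(n)
    depth_evidence = np.asarray(depth_evidence, dtype=np.float64)
    if depth_evidence.shape != (n,):
        raise ValueError("depth_evidence must give one extent per block")

    runs = _red_runs(labels)
    fired: list[str] = []

    def flank_green(idx: int) -> bool:
        return not (0 <= idx < n) or labels[idx] == "Normal"

    suppressed, surviving = [], []
    for start, stop in runs:
        short = (stop - start) < cfg.min_run
        if short and flank_green(start - 1) and flank_green(stop):
            suppressed.append((start, stop))
        else:
            surviving.append((start, stop))
    if suppressed:
        fired.append("scattered_fp_suppression")

    surviving_idx = [i for start, stop in surviving for i in range(start, stop)]
    red_fraction = len(surviving_idx) / n
    if red_fraction <= cfg.density_low:
        base = BASE_LOW
    elif red_fraction >= cfg.density_high:
        base = BASE_HIGH
        fired.append("dense_red")
    else:
        base = BASE_LOW + (BASE_HIGH - BASE_LOW) * (red_fraction - cfg.density_low) / (
            cfg.density_high - cfg.density_low
        )
        fired.append("intermediate_density")

    amp = 1.0
    yellow_adjacent = any(
        (i - 1 >= 0 and labels[i - 1] == "DamagedMatter") or (i + 1 < n and labels[i + 1] == "DamagedMatter")
        for i in surviving_idx
    )
    if yellow_adjacent:
        amp = cfg.neighbor_weight
        fired.append("yellow_neighborhood_amplification")

    if surviving_idx:
        extent = float(np.max(depth_evidence[surviving_idx]))
    else:
        extent = 1.0
    depth_factor = min(1.0, extent / cfg.depth_fraction)
    if depth_factor < 1.0:
        fired.append("shallow_evidence_attenuation")

    probability = float(np.clip(BASE_LOW + (base - BASE_LOW) * amp * depth_factor, 0.0, 1.0))
    call = "Tumor" if probability > cfg.decision_threshold else "WM"
    evidence = {
        "runs": runs,
        "suppressed_runs": suppressed,
        "surviving_runs": surviving,
        "red_fraction": red_fraction,
        "base_score": base,
        "yellow_adjacent": yellow_adjacent,
        "depth_extent": extent,
        "depth_factor": depth_factor,
        "fired_rules": fired,
    }
    return ScanVerdict(scan_id=segmap.scan_id, tumor_probability=probability, call=call, evidence=evidence)


@dataclass
class OverrideSummary:
    """Ledger of disagreements with the naive any-Red rule."""

    n_scans: int
    n_naive_positive: int
    n_overridden: int  # naive Tumor, filter WM
    n_confirmed: int  # naive Tumor, filter Tumor
    n_fp_scans: int  # truth WM but naive Tumor (needs ground truth)
    n_fp_overridden: int
    n_fp_confirmed: int
    overridden_ids: list[str]

    @property
    def fp_override_rate(self) -> float:
        """Fraction of algorithmic false-positive scans whose call the
        filter overrides to negative (NaN when there are none)."""
        if self.n_fp_scans == 0:
            return float("nan")
        return self.n_fp_overridden / self.n_fp_scans


def batch_verdicts(
    segmaps: list[SegmentationMap],
    cfg: FilterConfig | None = None,
) -> tuple[list[ScanVerdict], OverrideSummary]:
    """Score a cohort and tally overrides of the naive any-Red rule.

    A scan is *naive-positive* when any block is Tumor; an *override* is a
    naive-positive scan the filter calls WM.  When scans carry ground
    truth, overrides are additionally split over algorithmic false
    positives (truth WM, naive Tumor): overridden vs confirmed.
    """
    cfg = cfg or FilterConfig()
    verdicts = []
    n_naive = n_over = n_conf = n_fp = n_fp_over = n_fp_conf = 0
    overridden_ids = []
    for m in segmaps:
        v = score_scan(m, cfg=cfg)
        verdicts.append(v)
        naive_positive = any(lab == "Tumor" for lab in m.labels)
        if naive_positive:
            n_naive += 1
            if v.call == "WM":
                n_over += 1
                overridden_ids.append(m.scan_id)
            else:
                n_conf += 1
            if m.truth == "WM":
                n_fp += 1
                if v.call == "WM":
                    n_fp_over += 1
                else:
                    n_fp_conf += 1
    summary = OverrideSummary(
        n_scans=len(segmaps),
        n_naive_positive=n_naive,
        n_overridden=n_over,
        n_confirmed=n_conf,
        n_fp_scans=n_fp,
        n_fp_overridden=n_fp_over,
        n_fp_confirmed=n_fp_conf,
        overridden_ids=overridden_ids,
    )
    return verdicts, summary
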