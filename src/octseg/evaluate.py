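"""Multi-reader forced-choice diagnostic statistics.

Binary (White Matter vs Tumor) scan calls by one or more readers are
pooled into confusion counts, summarised as sensitivity / specificity /
global accuracy, and accompanied by inter-rater consistency (mean
pairwise agreement by default, Fleiss' kappa as an alternative).
Uncertainty is quantified by a non-parametric percentile bootstrap that
resamples *scans* with replacement (keeping each resampled scan's full
reader-call vector and truth, with the original scan count per
iteration) and reads the 2.5th / 97.5th percentiles of the resulting
empirical distribution.

Display values are whole percents rounded half-up; full precision is
retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

DEFAULT_BOOTSTRAP_ITERATIONS = 10_000


@dataclass
class AssessmentSet:
    """Complete scans x readers binary call matrix with ground truth.

    ``truth`` and ``calls`` are boolean with True = Tumor.  The matrix is
    rectangular and complete — the forced-choice design admits no missing
    entries.
    """

    scan_ids: list[str]
    truth: np.ndarray  # (n_scans,)
    reader_ids: list[str]
    calls: np.ndarray  # (n_scans, n_readers)

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        self.calls = np.asarray(self.calls, dtype=bool)
        n, r = len(self.scan_ids), len(self.reader_ids)
        if self.truth.shape != (n,):
            raise ValueError("truth must give one value per scan")
        if self.calls.shape != (n, r):
            raise ValueError(f"calls must be shape ({n}, {r}), got {self.calls.shape}")

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)

    @property
    def n_readers(self) -> int:
        return len(self.reader_ids)


@dataclass
class ConfusionCounts:
    """Assessment-level counts pooled over readers."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(assessments: AssessmentSet) -> ConfusionCounts:
    """Pooled confusion counts over all (scan, reader) assessments."""
    truth = assessments.truth[:, None]
    calls = assessments.calls
    return ConfusionCounts(
        tp=int((truth & calls).sum()),
        tn=int((~truth & ~calls).sum()),
        fp=int((~truth & calls).sum()),
        fn=int((truth & ~calls).sum()),
    )


def percent_round(proportion: float | None) -> float | None:
    """Half-up whole-percent rounding (0.745 -> 75), the display convention."""
    if proportion is None or (isinstance(proportion, float) and math.isnan(proportion)):
        return None
    return float(math.floor(100.0 * proportion + 0.5))


@dataclass
class Metrics:
    """Sensitivity / specificity / accuracy as proportions in [0, 1];
    a metric with a zero denominator is None (undefined), never 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            "sensitivity": percent_round(self.sensitivity),
            "specificity": percent_round(self.specificity),
            "accuracy": percent_round(self.accuracy),
        }


def metrics(counts: ConfusionCounts) -> Metrics:
    pos, neg = counts.tp + counts.fn, counts.tn + counts.fp
    return Metrics(
        sensitivity=counts.tp / pos if pos > 0 else None,
        specificity=counts.tn / neg if neg > 0 else None,
        accuracy=(counts.tp + counts.tn) / counts.total if counts.total > 0 else None,
    )


def _pairwise_agreement(calls: np.ndarray) -> float:
    n_scans, n_readers = calls.shape
    pairs = n_readers * (n_readers - 1) / 2
    pos = calls.sum(axis=1)
    concordant = pos * (pos - 1) / 2 + (n_readers - pos) * (n_readers - pos - 1) / 2
    return float(np.mean(concordant / pairs))


def consistency(assessments: AssessmentSet, method: str = "pairwise_agreement") -> float:
    """Inter-rater consistency of the reader panel.

    ``pairwise_agreement`` (default): mean over scans of the fraction of
    concordant reader pairs.  ``fleiss_kappa``: chance-corrected
    multi-rater agreement.  Both need >= 2 readers.
    """
    if assessments.n_readers < 2:
        raise ValueError("consistency needs >= 2 readers")
    if method == "pairwise_agreement":
        return _pairwise_agreement(assessments.calls)
    if method == "fleiss_kappa":
        table, _ = aggregate_raters(assessments.calls.astype(int), n_cat=2)
        return float(fleiss_kappa(table))
    raise ValueError(f"unknown consistency method {method!r}")


# Named statistics usable by the bootstrap: (truth, calls) -> float (NaN = undefined)


def _stat_sensitivity(truth: np.ndarray, calls: np.ndarray) -> float:
    pos = truth.sum() * calls.shape[1]
    return float((truth[:, None] & calls).sum() / pos) if pos > 0 else float("nan")


def _stat_specificity(truth: np.ndarray, calls: np.ndarray) -> float:
    neg = (~truth).sum() * calls.shape[1]
    return float((~truth[:, None] & ~calls).sum() / neg) if neg > 0 else float("nan")


def _stat_accuracy(truth: np.ndarray, calls: np.ndarray) -> float:
    return float((truth[:, None] == calls).mean())


def _stat_consistency(truth: np.ndarray, calls: np.ndarray) -> float:
    if calls.shape[1] < 2:
        return float("nan")
    return _pairwise_agreement(calls)


_NAMED_STATISTICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "sensitivity": _stat_sensitivity,
    "specificity": _stat_specificity,
    "accuracy": _stat_accuracy,
    "consistency": _stat_consistency,
}


@dataclass
class BootstrapResult:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    n_iterations: int
    seed: int
    unit: str
    n_undefined: int
    samples_mean: float
    samples_std: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def bootstrap_ci(
    assessments: AssessmentSet,
    statistic: str | Callable[[np.ndarray, np.ndarray], float],
    B: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    unit: str = "scan",
) -> BootstrapResult:
    """Percentile bootstrap CI of a panel statistic.

    ``unit="scan"`` (default) resamples scans with replacement, carrying
    each scan's full reader-call vector and truth and keeping the
    original scan count per iteration.  ``unit="assessment"`` resamples
    flattened (scan, reader) prediction pairs instead.  The CI is the
    empirical [2.5, 97.5] percentile interval; iterations where the
    statistic is undefined (e.g. a resample without positive scans) are
    dropped, and more than 50% undefined is an error.
    """
    stat_name = statistic if isinstance(statistic, str) else getattr(statistic, "__name__", "custom")
    stat_fn = _NAMED_STATISTICS[statistic] if isinstance(statistic, str) else statistic
    truth, calls = assessments.truth, assessments.calls
    point = stat_fn(truth, calls)
    rng = np.random.default_rng(seed)
    n = assessments.n_scans
    values = np.empty(B)
    if unit == "scan":
        for b in range(B):
            idx = rng.integers(0, n, n)
            values[b] = stat_fn(truth[idx], calls[idx])
    elif unit == "assessment":
        flat_truth = np.repeat(truth, assessments.n_readers)
        flat_calls = assessments.calls.reshape(-1)
        m = flat_truth.size
        for b in range(B):
            idx = rng.integers(0, m, m)
            values[b] = stat_fn(flat_truth[idx], flat_calls[idx][:, None])
    else:
        raise ValueError(f"unit must be 'scan' or 'assessment', got {unit!r}")
    defined = values[np.isfinite(values)]
    n_undefined = B - defined.size
    if n_undefined > B / 2:
        raise ValueError(
            f"statistic {stat_name!r} undefined in {n_undefined}/{B} bootstrap iterations "
            "(resamples routinely lack a truth class); the CI would be meaningless"
        )
    lo, hi = np.percentile(defined, [2.5, 97.5])
    return BootstrapResult(
        statistic=stat_name,
        point=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=B,
        seed=seed,
        unit=unit,
        n_undefined=int(n_undefined),
        samples_mean=float(defined.mean()),
        samples_std=float(defined.std()),
    )


@dataclass
class MetricReport:
    """One modality's point estimates with percentile CIs."""

    name: str
    estimates: dict[str, BootstrapResult] = field(default_factory=dict)


def evaluate_panel(
    assessments: AssessmentSet,
    name: str = "panel",
    B: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
    include_consistency: bool | None = None,
) -> MetricReport:
    """Full report for one reader panel: the three diagnostic metrics and
    (for >= 2 readers) consistency, each with a bootstrap CI."""
    if include_consistency is None:
        include_consistency = assessments.n_readers >= 2
    stats = ["sensitivity", "specificity", "accuracy"]
    if include_consistency:
        stats.append("consistency")
    report = MetricReport(name=name)
    for s in stats:
        report.estimates[s] = bootstrap_ci(assessments, s, B=B, seed=seed)
    return report


def compare_modalities(reports: list[MetricReport]) -> pd.DataFrame:
    """Pairwise comparison table of modality reports.

    One row per (metric, modality pair): point estimates, CIs, the point
    difference, and a CI-overlap flag.  Overlap is reported mechanically;
    no additional hypothesis test is layered on top.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to compare")
    rows = []
    for ra, rb in combinations(reports, 2):
        for metric_name in ra.estimates:
            if metric_name not in rb.estimates:
                continue
            ea, eb = ra.estimates[metric_name], rb.estimates[metric_name]
            overlap = (ea.ci_low <= eb.ci_high) and (eb.ci_low <= ea.ci_high)
            rows.append(
                {
                    "metric": metric_name,
                    "modality_a": ra.name,
                    "modality_b": rb.name,
                    "point_a": ea.point,
                    "ci_a_low": ea.ci_low,
                    "ci_a_high": ea.ci_high,
                    "point_b": eb.point,
                    "ci_b_low": eb.ci_low,
                    "ci_b_high": eb.ci_high,
                    "difference": ea.point - eb.point,
                    "ci_overlap": overlap,
                }
            )
    return pd.DataFrame(rows)
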