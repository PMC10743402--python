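"""Accuracy metrics, ROC AUC and score-distribution threshold analysis.

Conventions fixed here:

* sensitivity = tp / (tp + fn), specificity = tn / (tn + fp);
  balanced accuracy is their mean.
* "Predicted pathogenic" means probability strictly greater than the
  threshold.
* Box-plot statistics use Tukey fences — mild outliers beyond 1.5 x IQR,
  extreme outliers beyond 3 x IQR, both strict — with linear-interpolation
  quartiles, so a :class:`DistributionSummary` is reproducible bit for bit.

A metric whose denominator is empty is reported as undefined (``None``),
never as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "DistributionSummary",
    "ThresholdRow",
    "ThresholdSweep",
    "confusion_at_threshold",
    "metrics_from_counts",
    "roc_auc",
    "class_score_distribution",
    "threshold_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    accuracy: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def confusion_at_threshold(
    probabilities: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Confusion counts with 'pathogenic' called iff probability > threshold."""
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape != y.shape:
        raise ValueError(f"length mismatch: {probs.shape} vs {y.shape}")
    pred = probs > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, balanced accuracy and accuracy from counts."""
    sens = counts.tp / counts.positives if counts.positives else None
    spec = counts.tn / counts.negatives if counts.negatives else None
    ba = (sens + spec) / 2 if sens is not None and spec is not None else None
    acc = (counts.tp + counts.tn) / counts.n if counts.n else None
    return MetricsReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        accuracy=acc,
    )


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a random pathogenic variant scores above a
    random benign one, counting ties as one half.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


@dataclass
class DistributionSummary:
    """Tukey box-plot statistics for one class of prediction scores."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float  # smallest value inside the mild fences
    whisker_high: float  # largest value inside the mild fences
    mild_outliers: list[float] = field(default_factory=list)
    extreme_outliers: list[float] = field(default_factory=list)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _summarize(values: np.ndarray) -> DistributionSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    mild_lo, mild_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    ext_lo, ext_hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    inside = values[(values >= mild_lo) & (values <= mild_hi)]
    # strict fences: a point exactly on a fence is not an outlier
    extreme = values[(values < ext_lo) | (values > ext_hi)]
    mild = values[
        ((values < mild_lo) | (values > mild_hi))
        & (values >= ext_lo)
        & (values <= ext_hi)
    ]
    return DistributionSummary(
        minimum=float(values.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(values.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mild_outliers=sorted(float(v) for v in mild),
        extreme_outliers=sorted(float(v) for v in extreme),
    )


def class_score_distribution(
    probabilities: Sequence[float], labels: Sequence[int]
) -> dict[str, DistributionSummary]:
    """Per-class box-plot summaries of prediction scores.

    Supports threshold reasoning of the kind "most pathogenic variants
    score above x / most benign below y": the pathogenic whisker_low and
    benign whisker_high bound the non-outlying bulk of each class.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    out: dict[str, DistributionSummary] = {}
    for label, name in ((1, "pathogenic"), (0, "benign")):
        vals = probs[y == label]
        if vals.size == 0:
            raise ValueError(f"no {name} scores to summarize")
        out[name] = _summarize(vals)
    return out


@dataclass
class ThresholdRow:
    threshold: float
    counts: ConfusionCounts
    n_predicted_positive: int
    fp_share_pct: float | None  # fp / (tp+fp) as a percentage; None if no positives


@dataclass
class ThresholdSweep:
    rows: list[ThresholdRow]

    def to_dict(self) -> list[dict]:
        out = []
        for r in self.rows:
            d = asdict(r)
            d["counts"] = asdict(r.counts)
            out.append(d)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def threshold_report(
    probabilities: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float],
) -> ThresholdSweep:
    """Confusion counts and false-positive share across a threshold sweep."""
    rows = []
    for t in thresholds:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"threshold {t} outside [0, 1]")
        counts = confusion_at_threshold(probabilities, labels, t)
        n_pos = counts.tp + counts.fp
        share = 100.0 * counts.fp / n_pos if n_pos else None
        rows.append(
            ThresholdRow(
                threshold=float(t),
                counts=counts,
                n_predicted_positive=n_pos,
                fp_share_pct=share,
            )
        )
    return ThresholdSweep(rows=rows)
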