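"""The ConStruct classification model and position-ordered 5-fold CV.

The classifier is a bagged ensemble of decision trees with random feature
subsetting (a random forest) over the nine ConStruct predictors.  Cross
validation follows the position-ordered rule: variants are sorted by
protein position and fold labels 1..k are assigned cyclically along the
sequence, so every fold samples the whole protein rather than one
contiguous stretch.  Out-of-fold probabilities are pooled across folds
before metrics are computed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .annotation import (
    FEATURE_NAMES,
    AnnotationMap,
    SubstitutionMatrix,
    encode_variant,
)
from .evaluation import MetricsReport, confusion_at_threshold, metrics_from_counts, roc_auc
from .io import SAVRecord

__all__ = [
    "Hyperparameters",
    "TrainedModel",
    "FoldAssignment",
    "CVResult",
    "assign_position_folds",
    "features_frame",
    "train",
    "cross_validate",
]

SERIAL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class Hyperparameters:
    """Random-forest settings; defaults are the package's fixed choices."""

    n_trees: int = 500
    max_features_rule: str = "sqrt"  # sqrt | all | fraction
    max_features_fraction: float = 0.5
    min_leaf: int = 1
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_rule not in ("sqrt", "all", "fraction"):
            raise ValueError(f"unknown max_features_rule {self.max_features_rule!r}")

    def _sklearn_max_features(self):
        return {
            "sqrt": "sqrt",
            "all": None,
            "fraction": self.max_features_fraction,
        }[self.max_features_rule]


@dataclass(frozen=True)
class FoldAssignment:
    """Variant key -> fold label in 1..k."""

    folds: dict
    k: int

    def fold_of(self, record: SAVRecord) -> int:
        return self.folds[record.key]

    def sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.folds.values():
            counts[f - 1] += 1
        return counts


def assign_position_folds(records: Sequence[SAVRecord], k: int = 5) -> FoldAssignment:
    """Cyclic fold labels along the protein sequence.

    Records are sorted by ``(position, ref_aa, alt_aa)`` and labelled
    1, 2, ..., k, 1, 2, ... in that order.  The assignment is therefore
    deterministic and independent of input row order, and fold sizes
    differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not records:
        raise ValueError("no records to assign")
    if k > len(records):
        raise ValueError(f"k={k} exceeds number of records ({len(records)})")
    ordered = sorted(records, key=lambda r: r.key)
    folds = {rec.key: (i % k) + 1 for i, rec in enumerate(ordered)}
    if len(folds) != len(records):
        raise ValueError("duplicate variant keys in records")
    return FoldAssignment(folds=folds, k=k)


def features_frame(
    records: Sequence[SAVRecord], amap: AnnotationMap, matrix: SubstitutionMatrix
) -> pd.DataFrame:
    """Encode records into the canonical nine-column feature frame."""
    rows = [encode_variant(rec, amap, matrix).as_tuple() for rec in records]
    index = pd.MultiIndex.from_tuples(
        [rec.key for rec in records], names=["position", "ref_aa", "alt_aa"]
    )
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES), index=index)


def _labels_array(records: Sequence[SAVRecord]) -> np.ndarray:
    bad = [r for r in records if r.label not in ("pathogenic", "benign")]
    if bad:
        raise ValueError(
            f"{len(bad)} records are not labelled pathogenic/benign (first: "
            f"{bad[0].label!r})"
        )
    return np.array([1 if r.label == "pathogenic" else 0 for r in records])


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reproduce it."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    hyperparameters: Hyperparameters
    data_fingerprint: str

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Probability of pathogenicity per variant, in input row order."""
        if tuple(features.columns) != self.feature_names:
            raise ValueError(
                f"feature schema mismatch: model expects {self.feature_names}, "
                f"got {tuple(features.columns)}"
            )
        return self.estimator.predict_proba(features.to_numpy())[:, 1]

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": SERIAL_FORMAT_VERSION,
                "estimator": self.estimator,
                "feature_names": self.feature_names,
                "hyperparameters": asdict(self.hyperparameters),
                "data_fingerprint": self.data_fingerprint,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != SERIAL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')}"
            )
        return cls(
            estimator=payload["estimator"],
            feature_names=tuple(payload["feature_names"]),
            hyperparameters=Hyperparameters(**payload["hyperparameters"]),
            data_fingerprint=payload["data_fingerprint"],
        )


def _fingerprint(features: pd.DataFrame, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(features.to_csv().encode())
    h.update(labels.tobytes())
    return h.hexdigest()[:16]


def train(
    features: pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    hp: Hyperparameters = Hyperparameters(),
) -> TrainedModel:
    """Fit the forest; reproducible under a fixed seed."""
    labels = np.asarray(labels)
    if features.isna().any().any():
        raise ValueError("features contain NaN")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    est = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_features=hp._sklearn_max_features(),
        min_samples_leaf=hp.min_leaf,
        random_state=hp.seed,
        n_jobs=1,
    )
    est.fit(features.to_numpy(), labels)
    return TrainedModel(
        estimator=est,
        feature_names=tuple(features.columns),
        hyperparameters=hp,
        data_fingerprint=_fingerprint(features, labels),
    )


@dataclass
class CVResult:
    """Pooled out-of-fold probabilities plus per-fold and pooled metrics."""

    probabilities: pd.Series  # indexed by variant key, one out-of-fold value each
    labels: pd.Series
    assignment: FoldAssignment
    fold_reports: list[MetricsReport] = field(default_factory=list)
    pooled_report: MetricsReport | None = None


def cross_validate(
    records: Sequence[SAVRecord],
    amap: AnnotationMap,
    matrix: SubstitutionMatrix,
    hp: Hyperparameters = Hyperparameters(),
    k: int = 5,
    threshold: float = 0.5,
) -> CVResult:
    """Position-ordered k-fold CV with pooled out-of-fold metrics.

    Every variant is predicted exactly once, by the model trained on the
    k-1 folds that exclude it; confusion counts are taken at ``threshold``
    (predicted pathogenic iff probability strictly exceeds it).
    """
    assignment = assign_position_folds(records, k=k)
    features = features_frame(records, amap, matrix)
    labels = _labels_array(records)
    label_series = pd.Series(labels, index=features.index)
    oof = pd.Series(np.nan, index=features.index, dtype=float)
    fold_reports: list[MetricsReport] = []
    fold_labels = np.array([assignment.folds[key] for key in features.index])
    for fold in range(1, k + 1):
        test_mask = fold_labels == fold
        model = train(features[~test_mask], labels[~test_mask], hp)
        probs = model.predict_proba(features[test_mask])
        oof[test_mask] = probs
        fold_y = labels[test_mask]
        counts = confusion_at_threshold(probs, fold_y, threshold)
        report = metrics_from_counts(counts)
        if len(np.unique(fold_y)) == 2:
            report.auc = roc_auc(probs, fold_y)
        fold_reports.append(report)
    pooled_counts = confusion_at_threshold(oof.to_numpy(), labels, threshold)
    pooled = metrics_from_counts(pooled_counts)
    pooled.auc = roc_auc(oof.to_numpy(), labels)
    return CVResult(
        probabilities=oof,
        labels=label_series,
        assignment=assignment,
        fold_reports=fold_reports,
        pooled_report=pooled,
    )
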