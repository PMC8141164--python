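"""Confusion-matrix metrics, the subject split/CV protocol, and the
classifier x feature-percentage experiment report."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import ClassifierSpec, Prediction, predict, train
from .errors import ConfigurationError, DataError, SplitError
from .features import build_feature_table, feature_columns
from .selection import PERCENT_GRID, ZScoreScaler, percent_subset, relieff_rank

POSITIVE_LABEL = "PD"
LABELS = ("PD", "healthy")


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """Sensitivity/specificity/precision/accuracy; NaN flags an
    undefined metric (zero denominator)."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    training_accuracy: float = float("nan")


def confusion(
    preds: list[Prediction], positive_label: str = POSITIVE_LABEL
) -> ConfusionMatrix:
    if not preds:
        raise DataError("cannot build a confusion matrix from no predictions")
    cm = ConfusionMatrix()
    for p in preds:
        if p.actual not in LABELS or p.predicted not in LABELS:
            raise DataError(
                f"unknown label in prediction: {p.actual!r}/{p.predicted!r}"
            )
        actual_pos = p.actual == positive_label
        predicted_pos = p.predicted == positive_label
        if actual_pos and predicted_pos:
            cm.tp += 1
        elif actual_pos:
            cm.fn += 1
        elif predicted_pos:
            cm.fp += 1
        else:
            cm.tn += 1
    return cm


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """TP/(TP+FN), TN/(TN+FP), TP/(TP+FP), (TP+TN)/total."""
    if cm.total <= 0:
        raise DataError("empty confusion matrix")
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
    )


def split_subjects(
    table: pd.DataFrame, train_fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified subject-level random split.

    Per-class training quotas follow the largest-remainder rule so the
    overall training size is ceil(n * train_fraction) — 14 of 27 at the
    default fraction — and no subject appears on both sides.
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    labels = table["label"]
    class_counts = labels.value_counts()
    if (class_counts < 2).any() or len(class_counts) < 2:
        raise SplitError("each class needs at least 2 subjects to split")
    n_train = math.ceil(len(table) * train_fraction)
    quotas = {c: class_counts[c] * train_fraction for c in class_counts.index}
    base = {c: math.floor(q) for c, q in quotas.items()}
    leftover = n_train - sum(base.values())
    by_rem = sorted(
        quotas, key=lambda c: (-(quotas[c] - base[c]), -class_counts[c], str(c))
    )
    for c in by_rem[:leftover]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for c in sorted(class_counts.index):
        members = np.flatnonzero((labels == c).to_numpy())
        rng.shuffle(members)
        train_idx.extend(members[: base[c]])
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    return table.iloc[mask].reset_index(drop=True), table.iloc[~mask].reset_index(
        drop=True
    )


def _stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Round-robin per-class fold ids; folds may lack a class at small n."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    start = 0
    for c in sorted(set(labels)):
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        for j, idx in enumerate(members):
            assignment[idx] = (start + j) % folds
        start += len(members)
    return assignment


def crossvalidate(
    spec: ClassifierSpec,
    table: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
) -> tuple[MetricSet, ConfusionMatrix]:
    """Stratified k-fold CV with per-fold confusions pooled before metrics."""
    n = len(table)
    if folds > n:
        raise ConfigurationError(f"folds={folds} exceeds {n} rows")
    if folds < 2:
        raise ConfigurationError("need at least 2 folds")
    assignment = _stratified_folds(table["label"].to_numpy(), folds, seed)
    pooled = ConfusionMatrix()
    for fold in range(folds):
        test_mask = assignment == fold
        if not test_mask.any():
            continue
        model = train(spec, table.iloc[~test_mask])
        preds = predict(model, table.iloc[test_mask])
        pooled = pooled + confusion(preds)
    return metrics(pooled), pooled


@dataclass
class EvaluationReport:
    """Per (classifier, percentage) metrics plus split provenance."""

    table: pd.DataFrame
    ranking: pd.DataFrame
    train_ids: list[str]
    test_ids: list[str]
    seed: int


def evaluate_feature_table(
    features: pd.DataFrame,
    classifiers: list[ClassifierSpec],
    percentages: tuple[int, ...] = PERCENT_GRID,
    train_fraction: float = 0.5,
    folds: int = 10,
    relieff_k: int = 1,
    seed: int = 0,
    rank_on: str = "train",
) -> EvaluationReport:
    """Split, normalize, rank, then score every classifier x percentage.

    Normalization statistics and (by default) the ReliefF ranking come
    from the training half only; the four test metrics are a single
    evaluation on the held-out half, while training accuracy is the
    pooled k-fold CV accuracy inside the training half.
    """
    bad = set(percentages) - set(PERCENT_GRID)
    if bad:
        raise ConfigurationError(f"percentages outside the 10..100 grid: {bad}")
    if rank_on not in ("train", "all"):
        raise ConfigurationError("rank_on must be 'train' or 'all'")
    train_df, test_df = split_subjects(features, train_fraction, seed=seed)
    scaler = ZScoreScaler().fit(train_df)
    train_z = scaler.transform(train_df)
    test_z = scaler.transform(test_df)
    rank_table = (
        train_z if rank_on == "train" else pd.concat([train_z, test_z], axis=0)
    )
    ranked = relieff_rank(rank_table, k=relieff_k)
    total = len(feature_columns(train_z))
    rows = []
    for pct in percentages:
        subset = percent_subset(ranked, pct, total=total)
        keep = ["subject_id", "label", "hy"] + [
            c for c in ranked.order if c in subset
        ]
        tr = train_z[[c for c in train_z.columns if c in keep]]
        te = test_z[[c for c in test_z.columns if c in keep]]
        for spec in classifiers:
            cv_metrics, _ = crossvalidate(spec, tr, folds=folds, seed=seed)
            model = train(spec, tr)
            cm = confusion(predict(model, te))
            ms = metrics(cm)
            rows.append(
                {
                    "classifier": spec.kind,
                    "pct": pct,
                    "n_features": len(subset),
                    "training_accuracy": cv_metrics.accuracy,
                    "sensitivity": ms.sensitivity,
                    "specificity": ms.specificity,
                    "precision": ms.precision,
                    "accuracy": ms.accuracy,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                }
            )
    ranking = pd.DataFrame(
        {
            "feature": ranked.order,
            "weight": [ranked.scores[f] for f in ranked.order],
            "rank": np.arange(1, len(ranked.order) + 1),
        }
    )
    return EvaluationReport(
        table=pd.DataFrame(rows),
        ranking=ranking,
        train_ids=train_df["subject_id"].tolist(),
        test_ids=test_df["subject_id"].tolist(),
        seed=seed,
    )
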