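"""Performance metrics, ROC/AUC, summary-statistic t-tests, external validation.

The positive class for TP/precision/recall is CTL (= 1), matching the
pipeline's label convention (DEP = 0, CTL = 1); pass ``positive=0`` to swap.
The two-sample t-test works from group summary statistics (n, mean, SD) with
pooled variance, so published group tables can be checked without raw data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .features import FeatureParams, feature_table
from .io import Recording
from .preprocess import preprocess_recording
from .select import SelectionReport

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvalReport",
    "SummaryStats",
    "confusion_from_predictions",
    "f1_from_precision_recall",
    "metrics_from_counts",
    "roc_auc",
    "two_sample_t",
    "external_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Accuracy/precision/recall/F1; undefined metrics are NaN and flagged."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: tuple[str, ...] = ()


@dataclass
class SummaryStats:
    """Group summary: size, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2PR/(P+R); lets published P/R tables be re-derived."""
    if precision + recall == 0:
        raise ValueError("F1 undefined for precision + recall == 0")
    return 2.0 * precision * recall / (precision + recall)


def confusion_from_predictions(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics_from_counts(counts: ConfusionCounts) -> MetricSet:
    """Accuracy = (TP+TN)/total, Precision = TP/(TP+FP), Recall = TP/(TP+FN),
    F1 = 2*Precision*Recall/(Precision+Recall).

    Metrics with a zero denominator come back as NaN with their name in
    ``undefined`` instead of a silent 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero total counts")
    undefined = []
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        precision, und_p = math.nan, True
        undefined.append("precision")
    else:
        precision, und_p = counts.tp / (counts.tp + counts.fp), False
    if counts.tp + counts.fn == 0:
        recall, und_r = math.nan, True
        undefined.append("recall")
    else:
        recall, und_r = counts.tp / (counts.tp + counts.fn), False
    if und_p or und_r or (precision + recall) == 0:
        f1 = math.nan
        undefined.append("f1")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(accuracy, precision, recall, f1, tuple(undefined))


def roc_auc(probabilities, labels, positive: int = 1):
    """ROC points (FPR, TPR) over the threshold sweep and the trapezoid AUC.

    AUC equals the probability that a random positive outscores a random
    negative (the Mann-Whitney identity), which the tests verify against a
    brute-force pair count.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, np.float64)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(
        labels, probabilities, pos_label=positive, drop_intermediate=False
    )
    return list(zip(fpr.tolist(), tpr.tolist())), float(_auc(fpr, tpr))


def two_sample_t(group_a: SummaryStats, group_b: SummaryStats) -> tuple[float, int]:
    """Pooled-variance (Student) two-sample t from summary statistics.

    Returns ``(t, df)`` with df = nA + nB - 2. Pooling (not Welch) is the
    convention here because the degrees of freedom of published contrasts
    match it.
    """
    na, nb = group_a.n, group_b.n
    sp2 = ((na - 1) * group_a.sd**2 + (nb - 1) * group_b.sd**2) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t = (group_a.mean - group_b.mean) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(t), na + nb - 2


@dataclass
class EvalReport:
    """Confusion counts, scalar metrics, ROC curve and AUC for one model/dataset."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc: list[tuple[float, float]]
    auc: float
    n_windows: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["counts"] = asdict(self.counts)
        path.write_text(json.dumps(payload, indent=2))
        return path


def evaluate_predictions(y_true, proba_pos, positive: int = 1) -> EvalReport:
    """Threshold at 0.5, compute counts/metrics, and the ROC over scores."""
    y_true = np.asarray(y_true)
    proba_pos = np.asarray(proba_pos, np.float64)
    neg = np.setdiff1d(np.unique(np.asarray([0, 1])), [positive])[0]
    y_pred = np.where(proba_pos >= 0.5, positive, neg)
    counts = confusion_from_predictions(y_true, y_pred, positive)
    metrics = metrics_from_counts(counts)
    roc, auc_value = roc_auc(proba_pos, y_true, positive)
    return EvalReport(
        counts=counts,
        accuracy=metrics.accuracy,
        precision=metrics.precision,
        recall=metrics.recall,
        f1=metrics.f1,
        roc=roc,
        auc=auc_value,
        n_windows=int(y_true.size),
    )


def external_validate(
    model,
    recordings: list[Recording],
    selection: SelectionReport,
    params: FeatureParams | None = None,
    filter: bool = True,
    positive: int = 1,
) -> EvalReport:
    """Score a trained model on new recordings with the frozen training chain.

    Applies the training-time preprocessing, span, electrodes and feature
    combination from the selection report; nothing is refit. Recordings
    missing a selected electrode raise an error naming it.
    """
    feats = selection.combination_features
    X_rows, y_rows = [], []
    for rec in recordings:
        montage = {c.lower() for c in rec.channel_names}
        for electrode in selection.electrodes:
            if electrode.lower() not in montage:
                raise ValueError(
                    f"subject {rec.subject_id}: selected electrode {electrode!r} "
                    "missing from recording"
                )
        windows = preprocess_recording(
            rec, selection.span, selection.electrodes, filter=filter
        )
        table = feature_table(windows, params=params, features=feats)
        X_rows.append(table[feats].to_numpy())
        y_rows.append(table["y"].to_numpy())
    X = np.vstack(X_rows)
    y = np.concatenate(y_rows)
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    proba_pos = proba[:, classes.index(positive)]
    return evaluate_predictions(y, proba_pos, positive)
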