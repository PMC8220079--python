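"""Imbalance-aware evaluation: confusion matrix, macro metrics, recall
banding, and the noise-threshold grid search.

With roughly half of all windows belonging to the rest class, overall
accuracy alone rewards a classifier that just predicts rest. The headline
metric is therefore the macro recall — the unweighted mean of per-class
recalls, reported here (as is common in this literature) as the *balanced
accuracy*. Macro precision is the analogous mean of per-class precisions,
and the macro F1 is the harmonic mean of the two macro values (not the mean
of per-class F1 scores). Classes absent from the ground truth of a split
have undefined recall and are excluded from the macro averages; classes
present in the truth but never predicted contribute precision 0. All four
headline metrics are reported on the percent scale.

Per-class recalls are additionally banded at 0.8 and 0.6: movements below
80% recall are considered too unreliable for practical prosthesis use.

The threshold search scans a geometric grid of noise thresholds
(1e-4 down to 1e-12 by factors of 10), scoring each by balanced accuracy on
an inner repetition split of the *training* repetitions so that no
evaluation data influences the choice; an exact-replication mode that
scores on the test repetitions is available as a flag.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dnn import ClassifierSpec, TrainedClassifier, train
from .errors import EmgError, InputError
from .features import apply_standardizer, extract_features, fit_standardizer
from .recording import Recording
from .windowing import WindowSet, segment, split_by_repetition

__all__ = [
    "EvaluationReport",
    "ThresholdSearchResult",
    "DEFAULT_THRESHOLD_GRID",
    "RECALL_BANDS",
    "confusion_matrix",
    "compute_metrics",
    "band_recalls",
    "evaluate_predictions",
    "threshold_search",
]

#: Grid-search candidates: 1e-4 .. 1e-12 by factors of 10 (9 values).
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(10.0**-k for k in range(4, 13))

#: Band labels: closed lower bound at 0.8 ("≥ 0.8" is the practical band).
RECALL_BANDS: tuple[str, ...] = (">=0.8", "0.6-0.8", "<0.6")


@dataclass
class EvaluationReport:
    """Confusion matrix plus the derived metrics, percent scale."""

    confusion: np.ndarray
    class_list: np.ndarray
    overall_accuracy: float
    macro_recall: float
    macro_precision: float
    macro_f1: float
    per_class_recall: dict[int, float]
    recall_bands: dict[str, list[int]]
    excluded_classes: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def balanced_accuracy(self) -> float:
        """Alias: balanced accuracy is reported as the macro recall."""
        return self.macro_recall

    def to_dict(self) -> dict:
        return {
            "class_list": [int(c) for c in self.class_list],
            "confusion": self.confusion.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "macro_f1": self.macro_f1,
            "per_class_recall": {str(k): v for k, v in self.per_class_recall.items()},
            "recall_bands": self.recall_bands,
            "excluded_classes": self.excluded_classes,
            "meta": self.meta,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_matrix(
    y_true: Sequence[int], y_pred: Sequence[int], class_list: Sequence[int]
) -> np.ndarray:
    """K x K count matrix; rows are truth, columns are prediction, both
    indexed by position in ``class_list``."""
    y_true = np.asarray(y_true, dtype=np.int64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.int64).ravel()
    if y_true.size != y_pred.size:
        raise InputError(f"length mismatch: {y_true.size} truths vs {y_pred.size} predictions")
    classes = np.asarray([int(c) for c in class_list], dtype=np.int64)
    index = {int(c): i for i, c in enumerate(classes)}
    if len(index) != classes.size:
        raise InputError("class_list contains duplicates")
    unknown = (set(y_true.tolist()) | set(y_pred.tolist())) - set(index)
    if unknown:
        raise InputError(f"labels not in class_list: {sorted(unknown)}")
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    ti = np.array([index[v] for v in y_true.tolist()], dtype=np.int64)
    pi = np.array([index[v] for v in y_pred.tolist()], dtype=np.int64)
    np.add.at(cm, (ti, pi), 1)
    return cm


def compute_metrics(
    confusion: np.ndarray, class_list: Sequence[int] | None = None, exclude_rest: bool = False
) -> EvaluationReport:
    """Derive the report metrics from a confusion matrix.

    ``exclude_rest`` drops class 0 from the macro averages (the confusion
    matrix itself always keeps all classes).
    """
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise InputError("confusion matrix must be square")
    if cm.sum() == 0:
        raise InputError("confusion matrix is all zeros")
    if np.any(cm < 0):
        raise InputError("confusion counts must be non-negative")
    K = cm.shape[0]
    classes = (
        np.asarray(list(class_list), dtype=np.int64) if class_list is not None else np.arange(K)
    )
    if classes.size != K:
        raise InputError("class_list length must match confusion dimension")

    total = cm.sum()
    overall = 100.0 * np.trace(cm) / total

    row_sums = cm.sum(axis=1)
    col_sums = cm.sum(axis=0)
    present = row_sums > 0
    if exclude_rest:
        present &= classes != 0
    excluded = [int(c) for c in classes[row_sums == 0]]
    if not present.any():
        raise InputError("no class present in the ground truth")

    diag = np.diag(cm)
    recalls = np.where(row_sums > 0, diag / np.where(row_sums > 0, row_sums, 1), np.nan)
    precisions = np.where(col_sums > 0, diag / np.where(col_sums > 0, col_sums, 1), 0.0)

    macro_recall = 100.0 * float(np.mean(recalls[present]))
    macro_precision = 100.0 * float(np.mean(precisions[present]))
    denom = macro_precision + macro_recall
    macro_f1 = 2.0 * macro_precision * macro_recall / denom if denom > 0 else 0.0

    per_class = {int(c): float(recalls[i]) for i, c in enumerate(classes) if row_sums[i] > 0}
    return EvaluationReport(
        confusion=cm,
        class_list=classes,
        overall_accuracy=float(overall),
        macro_recall=macro_recall,
        macro_precision=macro_precision,
        macro_f1=float(macro_f1),
        per_class_recall=per_class,
        recall_bands=band_recalls(per_class),
        excluded_classes=excluded,
        meta={"exclude_rest": exclude_rest},
    )


def band_recalls(per_class_recall: dict[int, float]) -> dict[str, list[int]]:
    """Partition classes into recall bands >=0.8, [0.6, 0.8), <0.6."""
    bands: dict[str, list[int]] = {b: [] for b in RECALL_BANDS}
    for cls, r in sorted(per_class_recall.items()):
        if not 0.0 <= r <= 1.0:
            raise InputError(f"recall for class {cls} outside [0, 1]: {r}")
        if r >= 0.8:
            bands[">=0.8"].append(cls)
        elif r >= 0.6:
            bands["0.6-0.8"].append(cls)
        else:
            bands["<0.6"].append(cls)
    return bands


def evaluate_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], class_list: Sequence[int], exclude_rest: bool = False
) -> EvaluationReport:
    """Convenience: confusion matrix + metrics in one call."""
    cm = confusion_matrix(y_true, y_pred, class_list)
    return compute_metrics(cm, list(class_list), exclude_rest=exclude_rest)


@dataclass
class ThresholdSearchResult:
    grid: tuple[float, ...]
    score_per_threshold: dict[float, float]  # balanced accuracy, percent
    selected: float


def _score_threshold(
    train_ws: WindowSet, val_ws: WindowSet, T: float, spec: ClassifierSpec
) -> float:
    features_train = extract_features(train_ws, T)
    features_val = extract_features(val_ws, T)
    params = fit_standardizer(features_train)
    model = train(apply_standardizer(params, features_train), spec, standardizer=params)
    present = np.isin(features_val.labels, model.class_list)
    y_pred = model.classify_table(apply_standardizer(params, features_val))
    report = evaluate_predictions(
        features_val.labels[present], y_pred[present], model.class_list
    )
    return report.macro_recall


def threshold_search(
    recording: Recording,
    window_ms: float,
    stride_ms: float,
    spec: ClassifierSpec | None = None,
    grid: Iterable[float] = DEFAULT_THRESHOLD_GRID,
    train_reps: Iterable[int] = (1, 3, 4, 6),
    inner_train_reps: Iterable[int] = (1, 3, 4),
    inner_val_reps: Iterable[int] = (6,),
    channel_index: Iterable[int] | None = None,
    score_on_test: Iterable[int] | None = None,
    epochs: int = 20,
    seed: int = 0,
) -> ThresholdSearchResult:
    """Grid-search the ZC/SSC noise threshold by balanced accuracy.

    By default, scoring uses an inner split of the training repetitions
    ({1, 3, 4} to fit, {6} to score) so the held-out test repetitions stay
    untouched. Passing ``score_on_test`` (a repetition set) instead fits on
    all ``train_reps`` and scores on those repetitions — the
    exact-replication mode. Ties are broken toward the larger threshold.
    """
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise InputError("threshold grid must be non-empty")
    ws = segment(recording, window_ms, stride_ms, channel_index=channel_index)
    if score_on_test is not None:
        fit_ws, val_ws = split_by_repetition(ws, train_reps, score_on_test)
    else:
        train_ws, _ = split_by_repetition(ws, train_reps, ())
        fit_ws, val_ws = split_by_repetition(train_ws, inner_train_reps, inner_val_reps)

    n_classes = np.unique(fit_ws.labels).size
    if spec is None:
        # inner-split training sets are small; a modest batch keeps the
        # update count per epoch reasonable
        spec = ClassifierSpec(n_classes=n_classes, epochs=epochs, batch_size=64, seed=seed)

    scores: dict[float, float] = {}
    for T in grid:
        try:
            scores[T] = _score_threshold(fit_ws, val_ws, T, spec)
        except EmgError as exc:
            raise type(exc)(f"threshold search failed at T={T:g}: {exc}") from exc
    best = max(scores.values())
    selected = max(t for t, s in scores.items() if s == best)  # ties -> larger T
    return ThresholdSearchResult(grid=grid, score_per_threshold=scores, selected=selected)
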