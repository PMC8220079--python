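"""Config-driven experiment sweeps: window sizes x subjects x movement subsets.

One *cell* of a sweep is the full per-subject pipeline: segment the
recording at a window size, route windows into train/test by repetition,
optionally restrict to a movement subset, resolve the ZC/SSC noise
threshold (fixed value or inner-split grid search), extract and standardize
features (statistics fitted on the training split only), train the network,
and evaluate on the held-out repetitions. Per-subject modelling is the
default — one model per recording — matching how results are reported as
mean ± SD across subjects; a pooled mode that trains one model per window
size on all subjects' training windows exists but is off by default.

The default window-size grid is 100/200/400/800/1000 ms with a 100 ms
stride, except the 100 ms window which uses a 50 ms stride. Every source of
randomness in a sweep derives from the master seed, so a rerun with the
same config reproduces every metric exactly.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dnn import ClassifierSpec, train
from .errors import ConfigError
from .evaluation import (
    EvaluationReport,
    evaluate_predictions,
    threshold_search,
)
from .features import apply_standardizer, extract_features, fit_standardizer
from .io import read_ninapro_mat
from .recording import Recording
from .synth import SyntheticConfig, generate_dataset
from .windowing import SHAP_CLASSES, filter_movements, segment, split_by_repetition

__all__ = [
    "ExperimentConfig",
    "SweepReport",
    "default_stride_ms",
    "run_experiment",
    "shap_subset_experiment",
]

_METRICS = ("overall_accuracy", "macro_recall", "macro_precision", "macro_f1")


def default_stride_ms(window_ms: float) -> float:
    """100 ms stride, halved to 50 ms for the 100 ms window."""
    return 50.0 if window_ms <= 100 else 100.0


@dataclass
class ExperimentConfig:
    """Everything needed to run a sweep.

    Exactly one of ``synthetic`` / ``recording_paths`` supplies the data.
    ``threshold`` is either a number or the string ``"search"`` for the
    inner-split grid search; ``None`` resolves a dataset-tag default
    (0.01 for DB5-tagged recordings, 1e-8 otherwise).
    """

    synthetic: SyntheticConfig | None = None
    n_subjects: int = 1
    recording_paths: tuple[str, ...] = ()
    fs: float | None = None  # for MAT files that store no sampling rate
    channel_index: tuple[int, ...] | None = None
    window_ms_list: tuple[float, ...] = (100, 200, 400, 800, 1000)
    stride_ms: float | None = None  # None -> default_stride_ms rule
    threshold: float | str | None = None
    movements: str | tuple[int, ...] = "all"  # "all" | "shap" | explicit labels
    include_rest: bool = True
    exclude_rest_metrics: bool = False
    train_reps: tuple[int, ...] = (1, 3, 4, 6)
    test_reps: tuple[int, ...] = (2, 5)
    classifier_kwargs: dict = field(default_factory=dict)  # epochs=, batch_size=, ...
    pooled: bool = False
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (not self.recording_paths):
            raise ConfigError("provide exactly one of synthetic= or recording_paths=")
        if set(self.train_reps) & set(self.test_reps):
            raise ConfigError("train and test repetition sets overlap")
        if isinstance(self.movements, str) and self.movements not in ("all", "shap"):
            raise ConfigError("movements must be 'all', 'shap', or an explicit label tuple")


@dataclass
class SweepReport:
    """Per-(subject, window) evaluation reports plus cross-subject aggregates."""

    cells: dict[tuple[str, float], EvaluationReport]
    errors: dict[tuple[str, float], str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def aggregate(self) -> dict[float, dict[str, tuple[float, float]]]:
        """Per window size: (mean, population SD) across subjects per metric."""
        out: dict[float, dict[str, tuple[float, float]]] = {}
        windows = sorted({w for _, w in self.cells})
        for w in windows:
            reports = [r for (_, wi), r in self.cells.items() if wi == w]
            out[w] = {
                m: (
                    float(np.mean([getattr(r, m) for r in reports])),
                    float(np.std([getattr(r, m) for r in reports])),
                )
                for m in _METRICS
            }
        return out

    def to_summary_frame(self) -> pd.DataFrame:
        """Mean ± SD table shaped like the per-window-size results tables."""
        rows = []
        for w, metrics in self.aggregate().items():
            row: dict[str, object] = {"window_ms": w}
            for m, (mean, sd) in metrics.items():
                row[m] = f"{mean:.2f} ± {sd:.2f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "cells": {
                f"{s}|{w:g}": r.to_dict() for (s, w), r in sorted(self.cells.items())
            },
            "errors": {f"{s}|{w:g}": e for (s, w), e in sorted(self.errors.items())},
            "aggregate": {
                f"{w:g}": {m: list(v) for m, v in metrics.items()}
                for w, metrics in self.aggregate().items()
            },
            "meta": self.meta,
        }
        with open(os.fspath(path), "w") as fh:
            json.dump(payload, fh, indent=2)


def _load_recordings(config: ExperimentConfig) -> list[Recording]:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic, config.n_subjects)
    return [read_ninapro_mat(p, fs=config.fs) for p in config.recording_paths]


def _resolve_subset(config: ExperimentConfig) -> tuple[int, ...] | None:
    if config.movements == "all":
        return None
    if config.movements == "shap":
        return SHAP_CLASSES
    return tuple(int(m) for m in config.movements)


def _cell_seed(master_seed: int, subject_idx: int, window_idx: int) -> int:
    ss = np.random.SeedSequence([master_seed, subject_idx, window_idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _resolve_threshold(
    config: ExperimentConfig, recording: Recording, window_ms: float, stride_ms: float, seed: int
) -> float:
    if config.threshold == "search":
        result = threshold_search(
            recording,
            window_ms,
            stride_ms,
            channel_index=config.channel_index,
            train_reps=config.train_reps,
            seed=seed,
        )
        return result.selected
    if config.threshold is None:
        return 1e-2 if "DB5" in recording.source_tag.upper() else 1e-8
    return float(config.threshold)


class _Logger:
    def __init__(self, out_dir: str | None):
        self.path = os.path.join(out_dir, "log.jsonl") if out_dir else None
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)

    def __call__(self, **event) -> None:
        if self.path is None:
            return
        event["time"] = time.time()
        with open(self.path, "a") as fh:
            fh.write(json.dumps(event) + "\n")


def _run_cell(
    config: ExperimentConfig,
    recording: Recording,
    window_ms: float,
    stride_ms: float,
    seed: int,
    subset: tuple[int, ...] | None,
    log: _Logger,
) -> EvaluationReport:
    ws = segment(recording, window_ms, stride_ms, channel_index=config.channel_index)
    if subset is not None:
        ws = filter_movements(ws, subset, include_rest=config.include_rest)
    train_ws, test_ws = split_by_repetition(ws, config.train_reps, config.test_reps)
    T = _resolve_threshold(config, recording, window_ms, stride_ms, seed)
    table_train = extract_features(train_ws, T)
    table_test = extract_features(test_ws, T)
    params = fit_standardizer(table_train)  # training-split statistics only
    spec = ClassifierSpec(
        n_classes=int(np.unique(table_train.labels).size),
        seed=seed,
        **config.classifier_kwargs,
    )
    model = train(apply_standardizer(params, table_train), spec, standardizer=params)
    model.meta["threshold"] = T
    y_pred = model.classify_table(apply_standardizer(params, table_test))
    class_list = sorted(set(model.class_list.tolist()) | set(table_test.labels.tolist()))
    report = evaluate_predictions(
        table_test.labels, y_pred, class_list, exclude_rest=config.exclude_rest_metrics
    )
    report.meta.update(
        {
            "subject": recording.subject_id,
            "window_ms": window_ms,
            "stride_ms": stride_ms,
            "threshold": T,
            "n_train_windows": table_train.n_rows,
            "n_test_windows": table_test.n_rows,
            "seed": seed,
        }
    )
    log(
        stage="cell",
        subject=recording.subject_id,
        window_ms=window_ms,
        threshold=T,
        seed=seed,
        n_train=table_train.n_rows,
        n_test=table_test.n_rows,
        macro_recall=report.macro_recall,
    )
    return report


def _run_pooled(
    config: ExperimentConfig,
    recordings: list[Recording],
    window_ms: float,
    stride_ms: float,
    seed: int,
    subset: tuple[int, ...] | None,
    log: _Logger,
) -> dict[str, EvaluationReport]:
    """Train one model on the pooled training windows of all subjects,
    evaluate per subject."""
    per_subject: dict[str, tuple] = {}
    train_tables = []
    for rec in recordings:
        ws = segment(rec, window_ms, stride_ms, channel_index=config.channel_index)
        if subset is not None:
            ws = filter_movements(ws, subset, include_rest=config.include_rest)
        tr, te = split_by_repetition(ws, config.train_reps, config.test_reps)
        T = _resolve_threshold(config, rec, window_ms, stride_ms, seed)
        per_subject[rec.subject_id] = (extract_features(te, T), rec)
        train_tables.append(extract_features(tr, T))
    pooled_values = np.vstack([t.values for t in train_tables])
    pooled = type(train_tables[0])(
        values=pooled_values,
        names=train_tables[0].names,
        labels=np.concatenate([t.labels for t in train_tables]),
        repetitions=np.concatenate([t.repetitions for t in train_tables]),
        threshold_used=train_tables[0].threshold_used,
    )
    params = fit_standardizer(pooled)
    spec = ClassifierSpec(
        n_classes=int(np.unique(pooled.labels).size), seed=seed, **config.classifier_kwargs
    )
    model = train(apply_standardizer(params, pooled), spec, standardizer=params)
    reports = {}
    for subject, (table_test, _) in per_subject.items():
        y_pred = model.classify_table(apply_standardizer(params, table_test))
        class_list = sorted(set(model.class_list.tolist()) | set(table_test.labels.tolist()))
        reports[subject] = evaluate_predictions(
            table_test.labels, y_pred, class_list, exclude_rest=config.exclude_rest_metrics
        )
        log(stage="pooled-cell", subject=subject, window_ms=window_ms, seed=seed)
    return reports


def run_experiment(config: ExperimentConfig) -> SweepReport:
    """Run the full sweep; one failed cell is logged and skipped, the sweep
    continues."""
    recordings = _load_recordings(config)
    subset = _resolve_subset(config)
    log = _Logger(config.out_dir)
    cells: dict[tuple[str, float], EvaluationReport] = {}
    errors: dict[tuple[str, float], str] = {}

    for wi, window_ms in enumerate(config.window_ms_list):
        stride_ms = config.stride_ms if config.stride_ms is not None else default_stride_ms(window_ms)
        if config.pooled:
            seed = _cell_seed(config.seed, 0, wi)
            try:
                for subject, report in _run_pooled(
                    config, recordings, window_ms, stride_ms, seed, subset, log
                ).items():
                    cells[(subject, window_ms)] = report
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                errors[("pooled", window_ms)] = f"{type(exc).__name__}: {exc}"
                log(stage="error", window_ms=window_ms, error=str(exc))
            continue
        for si, rec in enumerate(recordings):
            seed = _cell_seed(config.seed, si, wi)
            try:
                cells[(rec.subject_id, window_ms)] = _run_cell(
                    config, rec, window_ms, stride_ms, seed, subset, log
                )
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                errors[(rec.subject_id, window_ms)] = f"{type(exc).__name__}: {exc}"
                log(stage="error", subject=rec.subject_id, window_ms=window_ms, error=str(exc))

    report = SweepReport(
        cells=cells,
        errors=errors,
        meta={
            "seed": config.seed,
            "movements": config.movements if isinstance(config.movements, str) else list(config.movements),
            "pooled": config.pooled,
            "window_ms_list": list(config.window_ms_list),
        },
    )
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        report.to_json(os.path.join(config.out_dir, "sweep_report.json"))
        report.to_summary_frame().to_csv(
            os.path.join(config.out_dir, "summary.csv"), index=False
        )
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(
                {
                    "seed": config.seed,
                    "n_subjects": len(recordings),
                    "window_ms_list": list(config.window_ms_list),
                    "cells": [f"{s}|{w:g}" for s, w in sorted(cells)],
                    "errors": [f"{s}|{w:g}" for s, w in sorted(errors)],
                },
                fh,
                indent=2,
            )
    return report


def shap_subset_experiment(config: ExperimentConfig) -> SweepReport:
    """Run the sweep restricted to the six SHAP prehensile-pattern classes.

    Raises :class:`ConfigError` naming any of the six classes missing from
    the data.
    """
    recordings = _load_recordings(config)
    present: set[int] = set()
    for rec in recordings:
        present |= set(rec.movement_classes().tolist())
    missing = sorted(set(SHAP_CLASSES) - present)
    if missing:
        raise ConfigError(f"SHAP subset classes missing from the data: {missing}")
    cfg = ExperimentConfig(**{**config.__dict__, "movements": "shap"})
    return run_experiment(cfg)
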