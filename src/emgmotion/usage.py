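"""Full-sequence usage simulation and prediction-continuity statistics.

A deployed myoelectric controller never sees pre-cut movement segments: it
classifies a sliding window over the raw stream, rest and transitions
included. :func:`simulate` applies a trained model across the entire length
of a recording and annotates each window with its majority ground-truth
label, yielding a :class:`UsageTrace`. Ideally the trace is a period of
rest followed by one long, continuous run of the intended movement.

:func:`continuity_stats` quantifies that: within each span of constant
non-rest truth, a configurable margin of windows at either end is treated
as transitional (windows there straddle the rest/movement boundary, so
errors are expected); wrong predictions strictly inside the remaining
interior are the harmful ones — each would make a prosthesis abruptly
switch movement mid-action. The default margin is 2 windows per side: one
window of boundary overlap plus one for majority-label lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dnn import TrainedClassifier
from .errors import InputError
from .features import apply_standardizer, extract_features
from .recording import Recording
from .windowing import segment

__all__ = ["UsageTrace", "ContinuityStats", "simulate", "continuity_stats"]


@dataclass
class UsageTrace:
    """Per-window predictions over an uncut recording."""

    window_start_s: np.ndarray
    predicted: np.ndarray
    truth: np.ndarray
    movement_spans: list[tuple[int, int, int]]  # (class, first window, last window) inclusive
    window_ms: float
    stride_ms: float

    @property
    def n_windows(self) -> int:
        return len(self.predicted)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.window_start_s, "truth": self.truth, "predicted": self.predicted}
        )


@dataclass
class ContinuityStats:
    """Continuity of predictions inside movement spans."""

    mid_movement_errors: int
    interior_windows: int
    transition_errors: int
    transition_windows: int
    longest_correct_run: int
    per_span: list[dict] = field(default_factory=list)

    @property
    def mid_movement_error_rate(self) -> float:
        """Fraction of interior windows predicted wrongly (0 when no interior)."""
        return self.mid_movement_errors / self.interior_windows if self.interior_windows else 0.0


def simulate(
    model: TrainedClassifier,
    recording: Recording,
    window_ms: float,
    stride_ms: float,
    threshold: float | None = None,
    channel_index: Iterable[int] | None = None,
    smoothing_k: int = 0,
) -> UsageTrace:
    """Slide the model over the whole recording, rest and transitions included.

    ``threshold`` defaults to the one the model was trained with. Ground
    truth is only used to annotate the trace, never to drive prediction.
    ``smoothing_k`` > 1 applies majority voting over the last k predictions
    (off by default; reported results elsewhere in the package are
    unsmoothed).
    """
    if threshold is None:
        threshold = float(model.meta.get("threshold", 0.0))
    ws = segment(recording, window_ms, stride_ms, channel_index=channel_index)
    table = extract_features(ws, threshold)
    if model.standardizer is None:
        raise InputError("model has no attached standardizer")
    if table.n_features != model.input_dim:
        raise InputError(
            f"recording yields {table.n_features} features but model expects {model.input_dim}"
        )
    predicted = model.predict(apply_standardizer(model.standardizer, table).values)
    if smoothing_k > 1:
        smoothed = predicted.copy()
        for i in range(len(predicted)):
            recent = predicted[max(0, i - smoothing_k + 1) : i + 1]
            vals, counts = np.unique(recent, return_counts=True)
            tied = vals[counts == counts.max()]
            smoothed[i] = tied[np.argmax([np.max(np.where(recent == t)[0]) for t in tied])]
        predicted = smoothed

    truth = ws.labels
    spans: list[tuple[int, int, int]] = []
    i = 0
    while i < len(truth):
        if truth[i] != 0:
            j = i
            while j + 1 < len(truth) and truth[j + 1] == truth[i]:
                j += 1
            spans.append((int(truth[i]), i, j))
            i = j + 1
        else:
            i += 1
    return UsageTrace(
        window_start_s=ws.start_indices / recording.fs,
        predicted=np.asarray(predicted),
        truth=truth.copy(),
        movement_spans=spans,
        window_ms=window_ms,
        stride_ms=stride_ms,
    )


def _longest_run(correct: np.ndarray) -> int:
    best = run = 0
    for c in correct:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


def continuity_stats(trace: UsageTrace, margin_windows: int = 2) -> ContinuityStats:
    """Count mid-movement vs transitional prediction errors per span."""
    if margin_windows < 0:
        raise InputError("margin_windows must be >= 0")
    mid_errors = 0
    interior_total = 0
    trans_errors = 0
    trans_total = 0
    longest = 0
    per_span: list[dict] = []
    for cls, start, end in trace.movement_spans:
        lo = start + margin_windows
        hi = end - margin_windows  # inclusive interior bounds
        interior = np.arange(lo, hi + 1) if hi >= lo else np.arange(0)
        margins = [k for k in range(start, end + 1) if k < lo or k > hi]
        correct = trace.predicted[interior] == cls if interior.size else np.zeros(0, dtype=bool)
        span_mid_err = int(np.count_nonzero(~correct))
        span_trans_err = int(sum(trace.predicted[k] != cls for k in margins))
        span_longest = _longest_run(correct)
        mid_errors += span_mid_err
        interior_total += interior.size
        trans_errors += span_trans_err
        trans_total += len(margins)
        longest = max(longest, span_longest)
        per_span.append(
            {
                "class": cls,
                "start": start,
                "end": end,
                "interior_windows": int(interior.size),
                "mid_movement_errors": span_mid_err,
                "transition_errors": span_trans_err,
                "longest_correct_run": span_longest,
            }
        )
    return ContinuityStats(
        mid_movement_errors=mid_errors,
        interior_windows=interior_total,
        transition_errors=trans_errors,
        transition_windows=trans_total,
        longest_correct_run=longest,
        per_span=per_span,
    )
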