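"""Sliding-window segmentation, repetition-wise splitting and movement subsetting.

A recording of N samples segmented with window length W and stride S (both in
samples, converted from ms by ``round(fs * ms / 1000)``) yields
``floor((N - W) / S) + 1`` windows at offsets 0, S, 2S, ...; the trailing
partial window is dropped. Each window receives the modal per-sample label;
ties are broken in favour of rest (label 0) when rest is among the tied
labels, otherwise the smallest class index — conservative toward
no-movement, since a spurious movement command is worse for a prosthesis
user than a missed one.

Train/test splitting follows the repetition protocol (repetitions 1, 3, 4, 6
for training; 2 and 5 for evaluation). Rest windows carry repetition index 0,
so they are routed by the repetition of the nearest preceding movement
sample, keeping the rest class represented in both splits; leading rest with
no preceding movement defaults to the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, InputError
from .recording import Recording

__all__ = [
    "WindowSet",
    "SHAP_CLASSES",
    "assign_label",
    "segment",
    "split_by_repetition",
    "filter_movements",
]

#: Movement classes representing the six SHAP prehensile patterns:
#: power sphere (27, spherical), writing tripod (26, tripod), prismatic
#: pinch (31, tip), large diameter (18, power), lateral (34), extension (36).
SHAP_CLASSES: tuple[int, ...] = (18, 26, 27, 31, 34, 36)


@dataclass
class WindowSet:
    """Segmented fixed-length windows with one label per window.

    ``routing_repetitions`` is the repetition index used for train/test
    routing: the window's own repetition for movement windows, the nearest
    preceding movement repetition for rest windows (-1 when none exists).
    """

    windows: np.ndarray  # (n_windows, window_len, n_channels)
    labels: np.ndarray  # (n_windows,)
    repetitions: np.ndarray  # (n_windows,) majority repetition (0 for rest)
    routing_repetitions: np.ndarray  # (n_windows,)
    start_indices: np.ndarray  # (n_windows,) sample offset of each window
    window_ms: float
    stride_ms: float
    fs: float
    channel_index: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[1]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def take(self, mask_or_indices: np.ndarray) -> "WindowSet":
        """Row-subset preserving order and metadata."""
        idx = np.asarray(mask_or_indices)
        return replace(
            self,
            windows=self.windows[idx],
            labels=self.labels[idx],
            repetitions=self.repetitions[idx],
            routing_repetitions=self.routing_repetitions[idx],
            start_indices=self.start_indices[idx],
        )


def assign_label(sample_labels: Sequence[int]) -> int:
    """Modal label of a window; ties break to 0 (rest) if tied, else the
    smallest tied class index."""
    arr = np.asarray(sample_labels, dtype=np.int64).ravel()
    if arr.size == 0:
        raise InputError("assign_label needs a non-empty sequence")
    values, counts = np.unique(arr, return_counts=True)
    tied = values[counts == counts.max()]
    return 0 if 0 in tied else int(tied.min())


def _ms_to_samples(fs: float, ms: float) -> int:
    return int(round(fs * ms / 1000.0))


def segment(
    recording: Recording,
    window_ms: float,
    stride_ms: float,
    channel_index: Iterable[int] | None = None,
    strict: bool = False,
) -> WindowSet:
    """Segment a recording into labelled sliding windows.

    Parameters
    ----------
    recording
        Source signal with per-sample annotations.
    window_ms, stride_ms
        Window length and hop in milliseconds; ``stride_ms`` must not exceed
        ``window_ms`` and must be at least one sample.
    channel_index
        Columns of ``recording.emg`` to keep (default: all). This is how a
        reduced electrode condition (e.g. one of two armbands) is expressed.
    strict
        When True, drop windows whose per-sample labels are not unanimous
        (transition windows are kept by default).
    """
    W = _ms_to_samples(recording.fs, window_ms)
    S = _ms_to_samples(recording.fs, stride_ms)
    if S < 1:
        raise InputError(f"stride of {stride_ms} ms is below one sample at fs={recording.fs}")
    if W < S:
        raise InputError(f"window ({window_ms} ms) must be at least the stride ({stride_ms} ms)")
    if channel_index is None:
        channel_index = tuple(range(recording.n_channels))
    channel_index = tuple(int(c) for c in channel_index)
    if any(c < 0 or c >= recording.n_channels for c in channel_index):
        raise InputError(f"channel_index out of range for {recording.n_channels} channels")

    emg = recording.emg[:, list(channel_index)]
    N = recording.n_samples
    if N < W:
        warnings.warn(f"recording shorter ({N} samples) than one window ({W}); empty WindowSet")
        empty = np.empty((0, W, len(channel_index)))
        zeros = np.zeros(0, dtype=np.int64)
        return WindowSet(empty, zeros, zeros.copy(), zeros.copy(), zeros.copy(),
                         window_ms, stride_ms, recording.fs, channel_index)

    n_windows = (N - W) // S + 1
    starts = np.arange(n_windows, dtype=np.int64) * S
    windows = sliding_window_view(emg, W, axis=0)[starts].transpose(0, 2, 1).copy()

    stim_view = sliding_window_view(recording.stimulus, W)[starts]
    rep_view = sliding_window_view(recording.repetition, W)[starts]
    labels = np.fromiter((assign_label(row) for row in stim_view), dtype=np.int64, count=n_windows)
    reps = np.fromiter((assign_label(row) for row in rep_view), dtype=np.int64, count=n_windows)

    # Routing repetition: forward-fill the repetition index of movement
    # samples; a rest window inherits the value at its start offset.
    movement = recording.stimulus > 0
    last = np.maximum.accumulate(np.where(movement, np.arange(N), -1))
    preceding_rep = np.where(last >= 0, recording.repetition[np.clip(last, 0, None)], -1)
    routing = np.where(labels > 0, reps, preceding_rep[starts])

    ws = WindowSet(windows, labels, reps, routing.astype(np.int64), starts,
                   window_ms, stride_ms, recording.fs, channel_index)
    if strict:
        unanimous = np.array([len(np.unique(row)) == 1 for row in stim_view])
        ws = ws.take(unanimous)
    return ws


def split_by_repetition(
    ws: WindowSet, train_reps: Iterable[int], test_reps: Iterable[int]
) -> tuple[WindowSet, WindowSet]:
    """Route windows into train/test by repetition index.

    Movement windows go by their own repetition; rest windows by the nearest
    preceding movement repetition (leading rest defaults to train). Windows
    whose routing repetition falls in neither set are dropped.
    """
    train_set, test_set = set(map(int, train_reps)), set(map(int, test_reps))
    if train_set & test_set:
        raise ConfigError(f"train and test repetition sets overlap: {sorted(train_set & test_set)}")
    routing = ws.routing_repetitions
    train_mask = np.isin(routing, sorted(train_set)) | (routing == -1)
    test_mask = np.isin(routing, sorted(test_set))
    return ws.take(train_mask), ws.take(test_mask)


def filter_movements(ws: WindowSet, keep: Iterable[int], include_rest: bool = True) -> WindowSet:
    """Keep windows whose label is in ``keep`` (plus rest if requested),
    preserving order."""
    keep_set = set(map(int, keep))
    if not keep_set:
        raise InputError("keep must be non-empty")
    mask = np.isin(ws.labels, sorted(keep_set))
    if include_rest:
        mask |= ws.labels == 0
    return ws.take(mask)
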