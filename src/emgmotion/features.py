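"""Time-domain sEMG features and feature standardization.

Six per-channel features are computed from each window, the classic
amplitude/turn statistics of myoelectric pattern recognition:

- **RMS** — root mean square, ``sqrt(mean(x^2))``.
- **MAV** — mean absolute value, ``mean(|x|)``.
- **MAVS** — MAV slope: the MAV of the second half of the window minus the
  MAV of the first half (two equal segments by default, keeping the feature
  count fixed at six per channel for every window size).
- **ZC** — zero crossings: adjacent-sample sign changes whose amplitude step
  ``|x_k - x_{k+1}|`` reaches the noise threshold ``T``. Signs are strict, so
  exact zeros never cross.
- **SSC** — slope sign changes: strict local extrema whose step to at least
  one neighbour reaches ``T``.
- **WL** — waveform length, ``sum(|x_{k+1} - x_k|)``.

ZC and SSC count occurrences, so low-amplitude noise would inflate them
without the threshold; ``T`` suppresses counts caused by fluctuations
smaller than the noise floor. Columns are standardized to zero mean / unit
variance using statistics fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .windowing import WindowSet

__all__ = [
    "FeatureTable",
    "StandardizationParams",
    "FEATURE_ORDER",
    "DEFAULT_THRESHOLDS",
    "zero_crossings",
    "slope_sign_changes",
    "amplitude_features",
    "extract_features",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]

#: Per-channel column order in extracted tables.
FEATURE_ORDER: tuple[str, ...] = ("rms", "mav", "mavs", "zc", "ssc", "wl")

#: Noise thresholds by dataset tag: 0.01 for the Myo-armband data (values as
#: stored), 1e-8 / 1e-6 for the high-rate Delsys data of intact / amputee
#: groups (grid-search optima).
DEFAULT_THRESHOLDS: dict[str, float] = {"DB5": 1e-2, "DB7-intact": 1e-8, "DB7-amputee": 1e-6}


@dataclass
class FeatureTable:
    """n_windows x (6 * n_channels) feature matrix with row annotations."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray
    repetitions: np.ndarray
    threshold_used: float
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetitions = np.asarray(self.repetitions, dtype=np.int64)
        if self.values.ndim != 2:
            raise InputError("values must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise InputError(f"{len(self.names)} names for {self.values.shape[1]} columns")
        if len(self.labels) != len(self.values) or len(self.repetitions) != len(self.values):
            raise InputError("labels/repetitions must align with rows")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InputError("feature values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["label"] = self.labels
        df["repetition"] = self.repetitions
        return df


def zero_crossings(x: np.ndarray, T: float) -> int:
    """Count threshold-gated zero crossings of a single-channel window."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InputError("zero_crossings needs at least 2 samples")
    if T < 0:
        raise InputError("threshold must be non-negative")
    a, b = x[:-1], x[1:]
    crossing = ((a < 0) & (b > 0)) | ((a > 0) & (b < 0))
    return int(np.count_nonzero(crossing & (np.abs(a - b) >= T)))


def slope_sign_changes(x: np.ndarray, T: float) -> int:
    """Count threshold-gated strict local extrema of a single-channel window."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise InputError("slope_sign_changes needs at least 3 samples")
    if T < 0:
        raise InputError("threshold must be non-negative")
    left, mid, right = x[:-2], x[1:-1], x[2:]
    extremum = ((mid > left) & (mid > right)) | ((mid < left) & (mid < right))
    gated = (np.abs(mid - right) >= T) | (np.abs(mid - left) >= T)
    return int(np.count_nonzero(extremum & gated))


def amplitude_features(x: np.ndarray, mavs_segments: int = 2) -> tuple[float, float, float, float]:
    """Return (rms, mav, mavs, wl) for a single-channel window.

    MAVS uses ``mavs_segments`` equal parts; with the default two, it is the
    second-half MAV minus the first-half MAV. With k segments the k-1
    adjacent differences are averaged so one value is returned regardless.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InputError("amplitude_features needs at least 2 samples")
    if mavs_segments < 2 or mavs_segments > x.size:
        raise InputError("mavs_segments must be in [2, window length]")
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    wl = float(np.sum(np.abs(np.diff(x))))
    bounds = [i * x.size // mavs_segments for i in range(mavs_segments + 1)]
    seg_mavs = [float(np.mean(np.abs(x[a:b]))) for a, b in zip(bounds, bounds[1:])]
    mavs = float(np.mean(np.diff(seg_mavs)))
    return rms, mav, mavs, wl


def extract_features(ws: WindowSet, T: float, mavs_segments: int = 2) -> FeatureTable:
    """Compute the six features for every window and channel.

    Columns are ordered per channel as ``(rms, mav, mavs, zc, ssc, wl)`` and
    named ``<feature>_<source column>``; rows align with the window set's
    labels and repetitions, and the threshold is recorded on the table.
    """
    if ws.window_len < 3:
        raise InputError("windows must have at least 3 samples for SSC")
    if T < 0:
        raise InputError("threshold must be non-negative")
    x = ws.windows  # (n, W, C)
    n, W, C = x.shape

    rms = np.sqrt(np.mean(x**2, axis=1))
    mav = np.mean(np.abs(x), axis=1)
    bounds = [i * W // mavs_segments for i in range(mavs_segments + 1)]
    seg = np.stack([np.abs(x[:, a:b, :]).mean(axis=1) for a, b in zip(bounds, bounds[1:])])
    mavs = np.diff(seg, axis=0).mean(axis=0)  # (n, C)
    wl = np.sum(np.abs(np.diff(x, axis=1)), axis=1)

    a, b = x[:, :-1, :], x[:, 1:, :]
    zc = np.count_nonzero(
        (((a < 0) & (b > 0)) | ((a > 0) & (b < 0))) & (np.abs(a - b) >= T), axis=1
    ).astype(float)
    left, mid, right = x[:, :-2, :], x[:, 1:-1, :], x[:, 2:, :]
    ssc = np.count_nonzero(
        (((mid > left) & (mid > right)) | ((mid < left) & (mid < right)))
        & ((np.abs(mid - right) >= T) | (np.abs(mid - left) >= T)),
        axis=1,
    ).astype(float)

    per_feature = {"rms": rms, "mav": mav, "mavs": mavs, "zc": zc, "ssc": ssc, "wl": wl}
    values = np.empty((n, 6 * C))
    names: list[str] = []
    for ci, col in enumerate(ws.channel_index):
        for fi, feat in enumerate(FEATURE_ORDER):
            values[:, 6 * ci + fi] = per_feature[feat][:, ci]
            names.append(f"{feat}_{col}")
    return FeatureTable(
        values=values,
        names=names,
        labels=ws.labels.copy(),
        repetitions=ws.repetitions.copy(),
        threshold_used=float(T),
    )


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean/std fitted on a training table (population std,
    divide by n). Zero-variance columns are flagged and only centered."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray  # boolean mask

    @property
    def n_features(self) -> int:
        return self.mean.size


def fit_standardizer(train: FeatureTable) -> StandardizationParams:
    """Fit per-column standardization statistics on a training table."""
    if train.n_rows < 2:
        raise InputError("standardizer needs at least 2 rows to fit")
    mean = train.values.mean(axis=0)
    std = train.values.std(axis=0)  # ddof=0, declared population estimator
    zero = std == 0.0
    std_safe = np.where(zero, 1.0, std)
    return StandardizationParams(mean=mean, std=std_safe, zero_variance=zero)


def apply_standardizer(params: StandardizationParams, table: FeatureTable) -> FeatureTable:
    """Transform a table with fitted (training) statistics."""
    if table.n_features != params.n_features:
        raise InputError(
            f"table has {table.n_features} features, standardizer was fit on {params.n_features}"
        )
    values = (table.values - params.mean) / params.std
    return FeatureTable(
        values=values,
        names=list(table.names),
        labels=table.labels.copy(),
        repetitions=table.repetitions.copy(),
        threshold_used=table.threshold_used,
        standardized=True,
        meta=dict(table.meta),
    )


def invert_standardizer(params: StandardizationParams, table: FeatureTable) -> FeatureTable:
    """Undo :func:`apply_standardizer` (exact up to floating-point rounding)."""
    if table.n_features != params.n_features:
        raise InputError("feature-dimension mismatch")
    values = table.values * params.std + params.mean
    return FeatureTable(
        values=values,
        names=list(table.names),
        labels=table.labels.copy(),
        repetitions=table.repetitions.copy(),
        threshold_used=table.threshold_used,
        standardized=False,
        meta=dict(table.meta),
    )
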