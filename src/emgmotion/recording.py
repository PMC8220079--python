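"""In-memory container for a multichannel sEMG recording.

A :class:`Recording` holds the raw signal matrix together with the per-sample
movement annotation (``stimulus``, 0 = rest) and repetition index
(``repetition``, 0 during rest, 1..n during a movement), plus acquisition
metadata. It is the common currency between the I/O layer, the synthetic
generator and the windowing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DataError, FormatError

__all__ = ["Recording"]


@dataclass
class Recording:
    """A labelled multichannel sEMG recording.

    Parameters
    ----------
    emg
        Signal matrix, shape ``(n_samples, n_channels)``, raw sensor units.
    fs
        Sampling rate in Hz.
    stimulus
        Per-sample integer movement label; 0 denotes rest.
    repetition
        Per-sample integer repetition index; 0 during rest, 1..n otherwise.
    subject_id, exercise_id, source_tag
        Free-text provenance metadata (e.g. ``source_tag="DB5"``).
    label_source
        Which annotation dialect the labels came from (``"stimulus"`` or the
        refined ``"restimulus"``); purely informational.
    """

    emg: np.ndarray
    fs: float
    stimulus: np.ndarray
    repetition: np.ndarray
    subject_id: str = "S1"
    exercise_id: str = "E1"
    source_tag: str = "synthetic"
    label_source: str = "stimulus"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.stimulus = np.asarray(self.stimulus).astype(np.int64).ravel()
        self.repetition = np.asarray(self.repetition).astype(np.int64).ravel()
        if self.emg.ndim != 2:
            raise FormatError(f"emg must be 2-D (n_samples, n_channels), got ndim={self.emg.ndim}")
        if self.emg.shape[0] == 0:
            raise FormatError("recording has 0 samples")
        if self.emg.shape[1] < 1:
            raise FormatError("recording needs at least 1 channel")
        n = self.emg.shape[0]
        if len(self.stimulus) != n or len(self.repetition) != n:
            raise AlignmentError(
                f"label vectors (stimulus={len(self.stimulus)}, repetition={len(self.repetition)}) "
                f"do not match n_samples={n}"
            )
        if not float(self.fs) > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        self.fs = float(self.fs)
        if not np.all(np.isfinite(self.emg)):
            raise DataError("emg contains non-finite values")
        if self.stimulus.min(initial=0) < 0 or self.repetition.min(initial=0) < 0:
            raise DataError("stimulus and repetition must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def movement_classes(self) -> np.ndarray:
        """Sorted non-rest movement labels present in the recording."""
        labels = np.unique(self.stimulus)
        return labels[labels > 0]
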