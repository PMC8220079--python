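"""Synthetic sEMG generator following the Ninapro acquisition protocol.

The generator emulates the *structure* of a Ninapro recording — per movement
class, 6 repetitions of 5 s activity each followed by 3 s of rest, with
per-sample stimulus and repetition annotations — using amplitude-modulated
Gaussian noise as the signal model. Surface EMG at rest is well described as
low-amplitude noise; during contraction its amplitude (not its mean) rises,
and which channels rise depends on which muscles the movement recruits. The
generator encodes exactly that: each movement class has a per-channel
``activation`` gain, and the signal is zero-mean Gaussian noise whose
standard deviation is ``baseline_noise_sd`` at rest and
``baseline_noise_sd * (1 + activation * (1 + jitter))`` during a movement,
with a fresh multiplicative jitter per repetition to mimic trial-to-trial
variability. No attempt is made to match real sEMG power spectra or
motor-unit physiology; amplitude structure is what the downstream
time-domain features measure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError
from .recording import Recording

__all__ = ["SyntheticConfig", "default_activation", "generate_recording", "generate_dataset"]


def default_activation(
    n_classes: int, n_channels: int, seed: int = 0, low: float = 0.5, high: float = 4.0
) -> np.ndarray:
    """Draw a (n_classes, n_channels) matrix of amplitude gains U(low, high).

    Independent uniform draws make distinct rows (and hence recoverable
    classes) almost sure; rows are re-drawn in the vanishingly unlikely event
    of a duplicate.
    """
    rng = np.random.default_rng(seed)
    act = rng.uniform(low, high, size=(n_classes, n_channels))
    while len(np.unique(act.round(12), axis=0)) < n_classes:  # pragma: no cover
        act = rng.uniform(low, high, size=(n_classes, n_channels))
    return act


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic acquisition protocol.

    Defaults mirror the Ninapro protocol: 5 s of activity then 3 s of rest,
    six repetitions per movement, and a DB5-like 8-channel armband at 200 Hz
    with ten movement classes.
    """

    n_channels: int = 8
    fs: float = 200.0
    movement_classes: tuple[int, ...] = tuple(range(1, 11))
    n_repetitions: int = 6
    movement_s: float = 5.0
    rest_s: float = 3.0
    activation: np.ndarray | None = None  # (n_classes, n_channels); derived from seed when None
    baseline_noise_sd: float = 0.01
    envelope_jitter_sd: float = 0.1
    inter_class_rest_s: float = 0.0  # extra rest padding after each class block
    seed: int = 0

    def __post_init__(self) -> None:
        if 0 in self.movement_classes:
            raise ConfigError("class label 0 is reserved for rest")
        if len(set(self.movement_classes)) != len(self.movement_classes):
            raise ConfigError("movement_classes must be distinct")
        if self.movement_s <= 0 or self.rest_s < 0 or self.inter_class_rest_s < 0:
            raise ConfigError("movement_s must be > 0 and rest durations >= 0")
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.baseline_noise_sd <= 0:
            raise ConfigError("baseline_noise_sd must be positive")
        if self.activation is None:
            self.activation = default_activation(len(self.movement_classes), self.n_channels, seed=self.seed)
        self.activation = np.asarray(self.activation, dtype=float)
        if self.activation.shape != (len(self.movement_classes), self.n_channels):
            raise ConfigError(
                f"activation must have shape (n_classes={len(self.movement_classes)}, "
                f"n_channels={self.n_channels}), got {self.activation.shape}"
            )
        if np.any(self.activation < 0):
            raise ConfigError("activation entries must be non-negative")
        if len(np.unique(self.activation.round(12), axis=0)) < len(self.movement_classes):
            raise ConfigError("distinct classes must have distinct activation rows")


def generate_recording(config: SyntheticConfig, subject_id: str = "S1") -> Recording:
    """Generate one recording: for each movement class, ``n_repetitions``
    blocks of activity each followed by a rest block, deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    move_len = round(config.movement_s * config.fs)
    rest_len = round(config.rest_s * config.fs)
    pad_len = round(config.inter_class_rest_s * config.fs)

    emg_blocks: list[np.ndarray] = []
    stim_blocks: list[np.ndarray] = []
    rep_blocks: list[np.ndarray] = []

    def rest_block(n: int) -> None:
        if n == 0:
            return
        emg_blocks.append(rng.normal(0.0, config.baseline_noise_sd, size=(n, config.n_channels)))
        stim_blocks.append(np.zeros(n, dtype=np.int64))
        rep_blocks.append(np.zeros(n, dtype=np.int64))

    for ci, cls in enumerate(config.movement_classes):
        for rep in range(1, config.n_repetitions + 1):
            jitter = rng.normal(0.0, config.envelope_jitter_sd)
            gains = 1.0 + config.activation[ci] * max(1.0 + jitter, 0.0)
            sd = config.baseline_noise_sd * gains  # per-channel
            emg_blocks.append(rng.normal(0.0, 1.0, size=(move_len, config.n_channels)) * sd)
            stim_blocks.append(np.full(move_len, cls, dtype=np.int64))
            rep_blocks.append(np.full(move_len, rep, dtype=np.int64))
            rest_block(rest_len)
        rest_block(pad_len)

    return Recording(
        emg=np.concatenate(emg_blocks, axis=0),
        fs=config.fs,
        stimulus=np.concatenate(stim_blocks),
        repetition=np.concatenate(rep_blocks),
        subject_id=subject_id,
        source_tag="synthetic",
    )


def generate_dataset(config: SyntheticConfig, n_subjects: int) -> list[Recording]:
    """Generate ``n_subjects`` recordings with identical label structure.

    Per-subject seeds are derived reproducibly from the master seed, and each
    subject's activation matrix is perturbed multiplicatively by
    ``envelope_jitter_sd`` to mimic between-subject amplitude variability.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    master = np.random.default_rng(config.seed)
    recordings = []
    for i in range(n_subjects):
        subject_seed = int(master.integers(0, 2**31 - 1))
        perturb = 1.0 + master.normal(0.0, config.envelope_jitter_sd, size=config.activation.shape)
        activation = np.clip(config.activation * np.clip(perturb, 0.05, None), 0.0, None)
        sub_cfg = replace(config, seed=subject_seed, activation=activation)
        recordings.append(generate_recording(sub_cfg, subject_id=f"S{i + 1}"))
    return recordings
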