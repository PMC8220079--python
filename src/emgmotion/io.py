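"""Ninapro-style MAT-file and feature-table I/O.

Reads recordings stored the way the Ninapro database distributes them: a MAT
file with an ``emg`` matrix plus per-sample ``stimulus``/``repetition``
vectors, where the refined, movement-aligned annotations are named
``restimulus``/``rerepetition``. Both the classic (v7) and the HDF5-backed
(v7.3) MAT dialects are supported; classic files go through
:func:`scipy.io.loadmat`, v7.3 through :mod:`h5py`.

The refined labels are preferred when present (they are the
Ninapro-recommended movement annotations); the choice is recorded on the
returned :class:`~emgmotion.recording.Recording` as ``label_source`` and can
be overridden with ``field_map``.

Sampling rate is not stored in all Ninapro files; when absent it must be
supplied by the caller (200 Hz for DB5, 2000 Hz for DB7).
"""

from __future__ import annotations

import os
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .errors import AlignmentError, DataError, FormatError
from .features import FeatureTable
from .recording import Recording

__all__ = [
    "read_ninapro_mat",
    "write_recording_mat",
    "read_feature_table",
    "write_feature_table",
]

#: Candidate field names per logical field, in preference order.
_DEFAULT_FIELDS = {
    "emg": ("emg",),
    "stimulus": ("restimulus", "stimulus"),
    "repetition": ("rerepetition", "repetition"),
    "fs": ("frequency", "fs"),
    "subject": ("subject",),
    "exercise": ("exercise",),
}


def _load_mat_variables(path: str) -> dict[str, np.ndarray]:
    """Load all top-level numeric variables from either MAT dialect."""
    try:
        raw = scipy.io.loadmat(path)
        return {k: np.asarray(v) for k, v in raw.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError) as scipy_err:
        # v7.3 files are HDF5; MATLAB stores arrays column-major, so the
        # on-disk shape is the transpose of the logical one.
        try:
            out: dict[str, np.ndarray] = {}
            with h5py.File(path, "r") as f:
                for key in f.keys():
                    node = f[key]
                    if isinstance(node, h5py.Dataset):
                        out[key] = np.asarray(node).T
            return out
        except OSError:
            raise FormatError(f"not a readable MAT file (either dialect): {path}") from scipy_err


def read_ninapro_mat(
    path: str | os.PathLike,
    field_map: Mapping[str, str] | None = None,
    fs: float | None = None,
) -> Recording:
    """Read a Ninapro-style MAT file into a :class:`Recording`.

    Parameters
    ----------
    path
        MAT file (classic v7 or v7.3/HDF5).
    field_map
        Optional overrides of on-disk variable names, keyed by logical name
        (``"emg"``, ``"stimulus"``, ``"repetition"``, ``"fs"``).
    fs
        Sampling rate in Hz, required when the file stores none.

    Raises
    ------
    FormatError
        A required field is missing (the message names it), or no sampling
        rate is available.
    AlignmentError
        Label vectors do not match the signal length.
    DataError
        The signal contains non-finite values.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    variables = _load_mat_variables(path)
    field_map = dict(field_map or {})

    def resolve(logical: str) -> tuple[str, np.ndarray] | None:
        if logical in field_map:
            name = field_map[logical]
            if name not in variables:
                raise FormatError(f"field_map names '{name}' for '{logical}' but the file has no such variable")
            return name, variables[name]
        for name in _DEFAULT_FIELDS[logical]:
            if name in variables:
                return name, variables[name]
        return None

    got_emg = resolve("emg")
    if got_emg is None:
        raise FormatError("missing required field 'emg'")
    emg = np.atleast_2d(np.asarray(got_emg[1], dtype=float))
    if emg.shape[0] == 1 and emg.shape[1] > 1:
        emg = emg.T

    got_stim = resolve("stimulus")
    if got_stim is None:
        raise FormatError("missing required field 'stimulus' (or 'restimulus')")
    stim_name, stimulus = got_stim

    got_rep = resolve("repetition")
    if got_rep is None:
        raise FormatError("missing required field 'repetition' (or 'rerepetition')")
    _, repetition = got_rep

    got_fs = resolve("fs")
    if got_fs is not None:
        fs_value = float(np.asarray(got_fs[1]).ravel()[0])
    elif fs is not None:
        fs_value = float(fs)
    else:
        raise FormatError("file stores no sampling rate; pass fs= or map it via field_map")

    stimulus = np.asarray(stimulus).ravel()
    repetition = np.asarray(repetition).ravel()
    if len(stimulus) != emg.shape[0] or len(repetition) != emg.shape[0]:
        raise AlignmentError(
            f"label lengths (stimulus={len(stimulus)}, repetition={len(repetition)}) "
            f"do not match emg n_samples={emg.shape[0]}"
        )
    if not np.all(np.isfinite(emg)):
        raise DataError("emg contains non-finite values")

    meta: dict = {}
    for logical in ("subject", "exercise"):
        got = resolve(logical) if logical not in field_map else None
        if got is not None:
            meta[logical] = np.asarray(got[1]).ravel()

    subject = str(int(meta["subject"][0])) if "subject" in meta and meta["subject"].size else "unknown"
    exercise = str(int(meta["exercise"][0])) if "exercise" in meta and meta["exercise"].size else "unknown"

    return Recording(
        emg=emg,
        fs=fs_value,
        stimulus=stimulus,
        repetition=repetition,
        subject_id=subject,
        exercise_id=exercise,
        source_tag=os.path.basename(path),
        label_source=stim_name,
    )


def write_recording_mat(recording: Recording, path: str | os.PathLike) -> None:
    """Write a :class:`Recording` as a classic MAT file readable by
    :func:`read_ninapro_mat` with default field names.

    Raises :class:`FormatError` on a 0-sample recording (``Recording``
    construction already forbids one, but callers may hand-build namespaces).
    """
    if recording.n_samples == 0:
        raise FormatError("refusing to write a recording with 0 samples")
    scipy.io.savemat(
        os.fspath(path),
        {
            "emg": recording.emg,
            "stimulus": recording.stimulus.reshape(-1, 1),
            "repetition": recording.repetition.reshape(-1, 1),
            "frequency": np.array([[recording.fs]]),
        },
    )


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    """Write a feature table as CSV: feature columns + ``label`` + ``repetition``."""
    names = list(table.names)
    if len(set(names)) != len(names):
        raise FormatError("duplicate feature column names")
    if "label" in names or "repetition" in names:
        raise FormatError("feature names may not shadow the 'label'/'repetition' columns")
    df = table.to_dataframe()
    df.to_csv(os.fspath(path), index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> FeatureTable:
    """Read a CSV written by :func:`write_feature_table`."""
    df = pd.read_csv(os.fspath(path))
    for required in ("label", "repetition"):
        if required not in df.columns:
            raise FormatError(f"feature table is missing the '{required}' column")
    names = [c for c in df.columns if c not in ("label", "repetition")]
    if len(set(names)) != len(names):
        raise FormatError("duplicate feature column names")
    values = df[names].to_numpy(dtype=float) if names else np.empty((len(df), 0))
    return FeatureTable(
        values=values,
        names=names,
        labels=df["label"].to_numpy(dtype=np.int64),
        repetitions=df["repetition"].to_numpy(dtype=np.int64),
        threshold_used=float("nan"),
    )
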