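"""Fixture-format epoch files and subject metadata tables.

The fixture format is one CSV per subject: columns ``trial_id``,
``stimulus_label``, ``correct``, ``channel``, then one column per time
sample labelled with its ms value.  One row per trial x channel.  Floats
are written with shortest-round-trip ``repr`` so files round-trip
bit-exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CHANNELS, EpochSet, StructuralError, SubjectProfile

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_metadata",
    "read_metadata",
    "profiles_to_frame",
]

_FIXED_COLS = ["trial_id", "stimulus_label", "correct", "channel"]


def write_epochs(epochs: EpochSet, path) -> Path:
    """Write one subject's epochs in the fixture CSV format."""
    path = Path(path)
    header = _FIXED_COLS + [f"{t:g}" for t in epochs.time_axis]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(epochs.n_trials):
            for ci, chan in enumerate(epochs.channels):
                writer.writerow(
                    [i, epochs.stimulus_label[i], int(epochs.correct[i]), chan]
                    + [repr(float(v)) for v in epochs.amplitudes[i, ci]]
                )
    return path


def read_epochs(path, subject_id: str | None = None) -> EpochSet:
    """Read a fixture CSV written by :func:`write_epochs`."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[: len(_FIXED_COLS)] != _FIXED_COLS:
            raise StructuralError(
                f"{path}: expected columns {_FIXED_COLS}, got {header[:4]}"
            )
        time_axis = np.array([float(c) for c in header[len(_FIXED_COLS):]])
        rows = list(reader)

    per_trial: dict[int, dict] = {}
    for row in rows:
        trial = int(row[0])
        label, correct, chan = row[1], bool(int(row[2])), row[3]
        if chan not in CHANNELS:
            raise StructuralError(f"{path}: unknown channel {chan!r}")
        entry = per_trial.setdefault(
            trial, {"label": label, "correct": correct, "data": {}}
        )
        entry["data"][chan] = np.array([float(v) for v in row[4:]])

    trial_ids = sorted(per_trial)
    n_samples = time_axis.size
    amplitudes = np.empty((len(trial_ids), len(CHANNELS), n_samples))
    labels, flags = [], []
    for k, trial in enumerate(trial_ids):
        entry = per_trial[trial]
        for ci, chan in enumerate(CHANNELS):
            if chan not in entry["data"]:
                raise StructuralError(
                    f"{path}: trial {trial} is missing channel {chan}"
                )
            amplitudes[k, ci] = entry["data"][chan]
        labels.append(entry["label"])
        flags.append(entry["correct"])

    epochs = EpochSet(
        subject_id=subject_id or path.stem,
        time_axis=time_axis,
        amplitudes=amplitudes,
        stimulus_label=np.array(labels, dtype="U16"),
        correct=np.array(flags, dtype=bool),
    )
    epochs.validate()
    return epochs


_META_COLS = [
    "subject_id", "group", "age", "sex", "education", "mmse",
    "attention", "language", "visuospatial", "memory", "frontal",
]


def profiles_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id, "group": p.group, "age": p.age,
            "sex": p.sex, "education": p.education, "mmse": p.mmse,
        }
        row.update({dom: p.snsb.get(dom, np.nan)
                    for dom in SubjectProfile.SNSB_DOMAINS})
        rows.append(row)
    return pd.DataFrame(rows, columns=_META_COLS)


def write_metadata(profiles: list[SubjectProfile], path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, index=False)
    return path


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: metadata lacks columns {missing}")
    return df
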