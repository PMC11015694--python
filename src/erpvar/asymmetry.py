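"""Normalized hemispheric asymmetry of the variability measures."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .rvc import MEASURE_NAMES

logger = logging.getLogger(__name__)

__all__ = ["asymmetry_index", "asymmetry_table"]


def asymmetry_index(value_fp2: float, value_fp1: float) -> float:
    """(Fp2 - Fp1) / (Fp2 + Fp1); positive means larger on the right.

    Both inputs must be finite and non-negative.  A zero channel sum makes
    the index undefined: it is reported as NaN with a logged reason.
    Dividing by the sum bounds the index to [-1, 1] and makes it invariant
    to a common positive scale.
    """
    if not (np.isfinite(value_fp2) and np.isfinite(value_fp1)):
        return float("nan")
    if value_fp2 < 0 or value_fp1 < 0:
        raise ValueError(
            f"asymmetry inputs must be non-negative, got "
            f"Fp2={value_fp2}, Fp1={value_fp1}"
        )
    total = value_fp2 + value_fp1
    if total == 0.0:
        logger.warning("asymmetry undefined: Fp2 + Fp1 = 0")
        return float("nan")
    return (value_fp2 - value_fp1) / total


def asymmetry_table(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-subject asymmetry indices from a tidy per-channel measures table.

    Expects columns subject_id, window, condition, channel and the four
    measures; returns one row per subject x window x condition with
    ``<measure>_asym`` columns.
    """
    fp1 = measures[measures["channel"] == "Fp1"].set_index(
        ["subject_id", "window", "condition"]
    )
    fp2 = measures[measures["channel"] == "Fp2"].set_index(
        ["subject_id", "window", "condition"]
    )
    common = fp1.index.intersection(fp2.index)
    rows = []
    for key in common:
        row = dict(zip(("subject_id", "window", "condition"), key))
        for m in MEASURE_NAMES:
            row[f"{m}_asym"] = asymmetry_index(
                fp2.loc[key, m], fp1.loc[key, m]
            )
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["subject_id", "window", "condition"]
        + [f"{m}_asym" for m in MEASURE_NAMES],
    )
    return out.sort_values(
        ["subject_id", "window", "condition"], ignore_index=True
    )
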