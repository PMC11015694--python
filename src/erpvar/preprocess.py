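"""Preprocessing: segmentation, baseline correction, trial selection,
amplitude-threshold artifact rejection, moving-average smoothing and the
subject-inclusion decision.

The pipeline order is fixed: segmentation -> baseline correction ->
correctness selection -> artifact rejection -> smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .datatypes import (
    CHANNELS,
    CONDITIONS,
    ConfigError,
    EpochSet,
    StructuralError,
)

logger = logging.getLogger(__name__)

EXCLUSION_NONE = "none"
EXCLUSION_NO_CLEAN = "no_clean_trials"
EXCLUSION_BELOW_HALF = "below_half_clean"


@dataclass
class ConditionChannelCounts:
    n_total: int
    n_correct: int
    n_clean: int

    @property
    def clean_fraction(self) -> float:
        return self.n_clean / self.n_total if self.n_total else 0.0


@dataclass
class PreprocessReport:
    """Per condition x channel trial accounting and the inclusion decision."""

    subject_id: str
    counts: dict[tuple[str, str], ConditionChannelCounts]
    included: bool
    exclusion_reason: str  # none | no_clean_trials | below_half_clean

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
            "counts": {
                f"{cond}/{chan}": {
                    "n_total": c.n_total,
                    "n_correct": c.n_correct,
                    "n_clean": c.n_clean,
                    "clean_fraction": c.clean_fraction,
                }
                for (cond, chan), c in self.counts.items()
            },
        }


def segment(
    continuous: np.ndarray,
    events: list[tuple[float, str]],
    sampling_rate: float = 250.0,
    span: tuple[float, float] = (-200.0, 800.0),
    subject_id: str = "",
    correct=None,
) -> EpochSet:
    """Cut a continuous (channels x samples) recording into epochs.

    Epoch sample ``k`` holds the continuous value at ``onset + (span[0] + k*dt)``
    ms.  Events whose epoch would run past a recording edge are skipped with
    a logged warning.  ``correct`` optionally supplies per-event correctness
    flags (default all-true).
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_channels, n_total = continuous.shape
    dt = 1000.0 / sampling_rate
    n_samples = int(round((span[1] - span[0]) / dt))
    offset = int(round(span[0] / dt))  # samples from onset to epoch start

    if correct is None:
        correct = [True] * len(events)
    trials, labels, flags = [], [], []
    for (onset_ms, label), ok in zip(events, correct):
        onset_idx = int(round(onset_ms / dt))
        start = onset_idx + offset
        stop = start + n_samples
        if start < 0 or stop > n_total:
            logger.warning(
                "event at %.1f ms (%s) skipped: epoch [%d, %d) outside "
                "recording of %d samples", onset_ms, label, start, stop, n_total,
            )
            continue
        trials.append(continuous[:, start:stop])
        labels.append(label)
        flags.append(bool(ok))

    amplitudes = (
        np.stack(trials) if trials else np.empty((0, n_channels, n_samples))
    )
    epochs = EpochSet(
        subject_id=subject_id,
        time_axis=span[0] + dt * np.arange(n_samples),
        amplitudes=amplitudes,
        stimulus_label=np.array(labels, dtype="U16"),
        correct=np.array(flags, dtype=bool),
        channels=CHANNELS[:n_channels],
    )
    return epochs


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window[0] <= t < window[1]``."""
    mask = (epochs.time_axis >= window[0]) & (epochs.time_axis < window[1])
    if not mask.any():
        raise StructuralError(
            f"no baseline samples in [{window[0]}, {window[1]}) ms"
        )
    baseline = epochs.amplitudes[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, amplitudes=epochs.amplitudes - baseline)


def select_correct_trials(epochs: EpochSet) -> EpochSet:
    """Keep only behaviourally correct trials (labels preserved)."""
    return epochs.select(epochs.correct)


def artifact_mask(
    epochs: EpochSet, threshold: float = 100.0, per_channel: bool = False
) -> np.ndarray:
    """Boolean keep mask: trial kept iff all samples satisfy |amp| <= threshold.

    With ``per_channel=True`` returns a (n_trials, n_channels) mask evaluated
    per channel; otherwise a (n_trials,) mask joint over both channels.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    within = np.abs(epochs.amplitudes) <= threshold
    if per_channel:
        return within.all(axis=2)
    return within.all(axis=(1, 2))


def reject_artifact_trials(
    epochs: EpochSet, threshold: float = 100.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials with any sample on any channel beyond ±threshold µV."""
    keep = artifact_mask(epochs, threshold=threshold, per_channel=False)
    return epochs.select(keep), keep


def smooth_trials(epochs: EpochSet, order: int = 9) -> EpochSet:
    """Centered moving average of ``order`` samples per trial and channel.

    At the edges the window shrinks to the available samples, so constant
    signals pass through unchanged.
    """
    if order % 2 == 0 or order < 1:
        raise ConfigError(f"order must be an odd positive integer, got {order}")
    n = epochs.n_samples
    if order > n:
        raise ConfigError(f"order {order} exceeds {n} samples")
    x = epochs.amplitudes
    half = order // 2
    # prepend a zero so cumsum differences give inclusive window sums
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    sums = csum[..., hi + 1] - csum[..., lo]
    smoothed = sums / (hi - lo + 1)
    return replace(epochs, amplitudes=smoothed)


def assess_inclusion(
    counts: dict[tuple[str, str], ConditionChannelCounts],
    subject_id: str = "",
    min_clean_fraction: float = 0.5,
) -> PreprocessReport:
    """Decide subject inclusion from per condition x channel trial counts.

    Excluded with reason ``no_clean_trials`` if any condition/channel has
    zero clean trials, else ``below_half_clean`` if any clean fraction is
    strictly below ``min_clean_fraction`` (exactly at the threshold is
    included).
    """
    for key, c in counts.items():
        if not 0 <= c.n_clean <= c.n_correct <= c.n_total:
            raise StructuralError(f"inconsistent counts for {key}: {c}")
    if any(c.n_clean == 0 for c in counts.values()):
        reason = EXCLUSION_NO_CLEAN
    elif any(c.clean_fraction < min_clean_fraction for c in counts.values()):
        reason = EXCLUSION_BELOW_HALF
    else:
        reason = EXCLUSION_NONE
    included = reason == EXCLUSION_NONE
    if not included:
        logger.info("subject %s excluded: %s", subject_id, reason)
    return PreprocessReport(
        subject_id=subject_id,
        counts=counts,
        included=included,
        exclusion_reason=reason,
    )


def preprocess_epochs(
    epochs: EpochSet,
    threshold: float = 100.0,
    smoothing_order: int = 9,
    smooth: bool = True,
    min_clean_fraction: float = 0.5,
) -> tuple[EpochSet, PreprocessReport]:
    """Run the fixed preprocessing chain on already-segmented epochs.

    Returns the clean, smoothed epoch set together with the per-condition
    trial accounting and inclusion decision.  Under the joint artifact rule
    both channels share the same clean-trial counts; they are reported per
    channel regardless.
    """
    epochs.validate()
    corrected = baseline_correct(epochs)
    correct_only = select_correct_trials(corrected)
    clean, _ = reject_artifact_trials(correct_only, threshold=threshold)
    out = smooth_trials(clean, order=smoothing_order) if smooth else clean

    counts: dict[tuple[str, str], ConditionChannelCounts] = {}
    for cond in CONDITIONS:
        n_total = int(epochs.condition_mask(cond).sum())
        n_correct = int(correct_only.condition_mask(cond).sum())
        n_clean = int(clean.condition_mask(cond).sum())
        for chan in epochs.channels:
            counts[(cond, chan)] = ConditionChannelCounts(
                n_total=n_total, n_correct=n_correct, n_clean=n_clean
            )
    report = assess_inclusion(
        counts, subject_id=epochs.subject_id, min_clean_fraction=min_clean_fraction
    )
    return out, report
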