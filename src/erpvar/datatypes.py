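"""Core data containers shared across the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CHANNELS = ("Fp1", "Fp2")
CONDITIONS = ("target", "standard")

#: Canonical analysis windows in ms (inclusive of both endpoints).
DEFAULT_WINDOWS = {"P2": (150.0, 300.0), "P3": (300.0, 600.0)}


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class StructuralError(ValueError):
    """Input data violates a structural precondition (grid, span, labels)."""


class InsufficientDataError(ValueError):
    """Too few trials/values to compute the requested quantity."""


@dataclass
class EpochSet:
    """Epoched two-channel EEG for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    time_axis : ndarray, shape (n_samples,)
        Time in ms relative to stimulus onset; strictly increasing,
        uniform step.
    amplitudes : ndarray, shape (n_trials, n_channels, n_samples)
        Trial amplitudes in µV.
    stimulus_label : ndarray of str, shape (n_trials,)
        Per-trial label, ``"target"`` or ``"standard"``.
    correct : ndarray of bool, shape (n_trials,)
        Behavioural-correctness flag per trial.
    channels : tuple of str
        Ordered channel names; ``("Fp1", "Fp2")``.
    """

    subject_id: str
    time_axis: np.ndarray
    amplitudes: np.ndarray
    stimulus_label: np.ndarray
    correct: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.stimulus_label = np.asarray(self.stimulus_label)
        self.correct = np.asarray(self.correct, dtype=bool)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`StructuralError` on any structural violation."""
        if self.amplitudes.ndim != 3:
            raise StructuralError(
                f"amplitudes must be 3-d (trials, channels, samples); got "
                f"shape {self.amplitudes.shape}"
            )
        n_trials, n_channels, n_samples = self.amplitudes.shape
        if n_channels != len(self.channels):
            raise StructuralError(
                f"channel axis length {n_channels} != {len(self.channels)} "
                "channel names"
            )
        if self.time_axis.shape != (n_samples,):
            raise StructuralError("time_axis length mismatch with amplitudes")
        if n_samples >= 2:
            steps = np.diff(self.time_axis)
            if not np.all(steps > 0):
                raise StructuralError("time axis must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise StructuralError("time axis must have a constant step")
        if self.stimulus_label.shape != (n_trials,):
            raise StructuralError("stimulus_label length mismatch")
        if self.correct.shape != (n_trials,):
            raise StructuralError("correct length mismatch")
        bad = set(np.unique(self.stimulus_label)) - set(CONDITIONS)
        if bad:
            raise StructuralError(f"unknown stimulus labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.amplitudes)):
            raise StructuralError("amplitudes contain non-finite values")

    # -- convenience --------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[2]

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise StructuralError(f"unknown channel {channel!r}") from None

    def condition_mask(self, condition: str) -> np.ndarray:
        if condition not in CONDITIONS:
            raise StructuralError(f"unknown condition {condition!r}")
        return self.stimulus_label == condition

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Return a new :class:`EpochSet` keeping trials where mask is true."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            amplitudes=self.amplitudes[mask],
            stimulus_label=self.stimulus_label[mask],
            correct=self.correct[mask],
        )

    def copy(self) -> "EpochSet":
        return replace(
            self,
            time_axis=self.time_axis.copy(),
            amplitudes=self.amplitudes.copy(),
            stimulus_label=self.stimulus_label.copy(),
            correct=self.correct.copy(),
        )


def canonical_time_axis(
    sampling_rate: float = 250.0, span: tuple[float, float] = (-200.0, 800.0)
) -> np.ndarray:
    """Half-open epoch grid [span[0], span[1]) at the given sampling rate.

    At 250 Hz over [-200, 800) this yields 250 samples, step 4 ms, with
    0 ms (stimulus onset) on-grid as the first post-stimulus sample.
    """
    dt = 1000.0 / sampling_rate
    n = int(round((span[1] - span[0]) / dt))
    return span[0] + dt * np.arange(n)


@dataclass
class SubjectProfile:
    """Demographics and neuropsychological scores for one subject."""

    subject_id: str
    group: str  # "CN" | "MCI"
    age: float
    sex: str  # "F" | "M"
    education: float
    mmse: float
    snsb: dict[str, float] = field(default_factory=dict)

    SNSB_DOMAINS = ("attention", "language", "visuospatial", "memory", "frontal")

    def validate(self) -> None:
        if self.group not in ("CN", "MCI"):
            raise ConfigError(f"group must be CN or MCI, got {self.group!r}")
        if not 0 <= self.mmse <= 30:
            raise ConfigError(f"mmse must be in [0, 30], got {self.mmse}")
        if self.age <= 0:
            raise ConfigError(f"age must be positive, got {self.age}")
        if self.sex not in ("F", "M"):
            raise ConfigError(f"sex must be F or M, got {self.sex!r}")


@dataclass
class RVCCurve:
    """Across-trial variance of single-trial amplitudes at each time point."""

    subject_id: str
    condition: str
    channel: str
    time_axis: np.ndarray
    variance: np.ndarray  # µV² per sample
    n_trials: int

    def __post_init__(self) -> None:
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)

    def validate(self) -> None:
        if self.variance.shape != self.time_axis.shape:
            raise StructuralError("variance/time_axis length mismatch")
        if np.any(self.variance < 0):
            raise StructuralError("variance must be non-negative")
        if self.n_trials < 2:
            raise InsufficientDataError(
                f"RVC requires >= 2 trials, got {self.n_trials}"
            )
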