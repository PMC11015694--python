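"""Response variance curves and their window measures.

The RVC is the pointwise across-trial (unbiased, n-1 denominator) variance
of single-trial amplitudes — the variability of trials around the average
ERP at each time point.  From the RVC four measures are extracted per
analysis window: peak variance (AMPV, µV²), its latency (LATV, ms), the 50%
fractional-area latency (FALV, ms) and the area under the curve
(AUCV, µV²·ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .datatypes import EpochSet, InsufficientDataError, RVCCurve, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "WindowMeasures",
    "compute_rvc",
    "extract_window_measures",
    "check_discernible_peak",
    "average_channel_measures",
    "flag_extreme_values",
]

MEASURE_NAMES = ("ampv", "latv", "falv", "aucv")


@dataclass
class WindowMeasures:
    ampv: float  # peak variance in window, µV²
    latv: float  # latency of that peak, ms (earliest on ties)
    falv: float  # 50% fractional-area latency, ms (NaN if AUCV == 0)
    aucv: float  # trapezoidal area of variance over the window, µV²·ms

    def as_dict(self) -> dict[str, float]:
        return {"ampv": self.ampv, "latv": self.latv,
                "falv": self.falv, "aucv": self.aucv}


def compute_rvc(epochs: EpochSet, condition: str, channel: str) -> RVCCurve:
    """Across-trial sample variance (ddof=1) at each time point."""
    mask = epochs.condition_mask(condition)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(
            f"{epochs.subject_id}: {condition}/{channel} has {n} trials; "
            "need >= 2 for the variance curve"
        )
    data = epochs.amplitudes[mask, epochs.channel_index(channel), :]
    variance = np.var(data, axis=0, ddof=1)
    return RVCCurve(
        subject_id=epochs.subject_id,
        condition=condition,
        channel=channel,
        time_axis=epochs.time_axis.copy(),
        variance=variance,
        n_trials=n,
    )


def _window_slice(rvc: RVCCurve, window: tuple[float, float]):
    lo, hi = window
    if lo >= hi:
        raise StructuralError(f"window {window} is empty")
    t = rvc.time_axis
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise StructuralError(
            f"window {window} outside epoch span [{t[0]}, {t[-1]}] ms"
        )
    idx = np.flatnonzero((t >= lo - 1e-9) & (t <= hi + 1e-9))
    if idx.size < 2:
        raise InsufficientDataError(f"window {window} covers < 2 samples")
    return idx


def extract_window_measures(
    rvc: RVCCurve, window: tuple[float, float]
) -> WindowMeasures:
    """AMPV, LATV, FALV and AUCV of the variance curve over one window.

    Window membership is inclusive of both endpoints.  FALV interpolates
    linearly on the cumulative trapezoid; with zero area it is undefined
    and reported as NaN.
    """
    idx = _window_slice(rvc, window)
    t = rvc.time_axis[idx]
    v = rvc.variance[idx]

    peak = int(np.argmax(v))  # argmax returns the earliest maximum
    ampv = float(v[peak])
    latv = float(t[peak])
    cum = cumulative_trapezoid(v, t, initial=0.0)
    aucv = float(cum[-1])

    if aucv <= 0.0:
        falv = float("nan")
        logger.warning(
            "%s %s/%s: zero area in window %s; FALV undefined",
            rvc.subject_id, rvc.condition, rvc.channel, window,
        )
    else:
        half = 0.5 * aucv
        j = int(np.searchsorted(cum, half))
        if j == 0:
            falv = float(t[0])
        else:
            c0, c1 = cum[j - 1], cum[j]
            frac = 0.0 if c1 == c0 else (half - c0) / (c1 - c0)
            falv = float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return WindowMeasures(ampv=ampv, latv=latv, falv=falv, aucv=aucv)


def check_discernible_peak(rvc: RVCCurve, window: tuple[float, float]) -> bool:
    """True iff the in-window maximum sits strictly inside the window and is
    a strict local maximum relative to its grid neighbours."""
    idx = _window_slice(rvc, window)
    v_win = rvc.variance[idx]
    k = int(np.argmax(v_win))
    if k == 0 or k == v_win.size - 1:
        return False
    g = idx[k]  # global grid index; interior of window implies 0 < g < n-1
    v = rvc.variance
    return bool(v[g] > v[g - 1] and v[g] > v[g + 1])


def average_channel_measures(m_fp1: float, m_fp2: float) -> float:
    """Arithmetic mean of one measure across the two channels.

    NaN (missing) in either channel propagates to a missing average.
    """
    if not (np.isfinite(m_fp1) and np.isfinite(m_fp2)):
        return float("nan")
    return 0.5 * (m_fp1 + m_fp2)


def flag_extreme_values(
    values, k: float = 3.0
) -> np.ndarray:
    """Tukey-fence screen: flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    NaN entries are never flagged.  A degenerate distribution (IQR = 0)
    yields no flags and a logged warning.  Requires >= 4 finite values.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise InsufficientDataError(
            f"extreme-value screen needs >= 4 finite values, got {finite.sum()}"
        )
    q1, q3 = np.percentile(values[finite], [25.0, 75.0])
    iqr = q3 - q1
    if iqr == 0.0:
        logger.warning("degenerate distribution (IQR = 0); no extreme flags")
        return np.zeros(values.shape, dtype=bool)
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = np.zeros(values.shape, dtype=bool)
    flags[finite] = (values[finite] < lo) | (values[finite] > hi)
    return flags
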