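"""Minimal EDF+C reader/writer for two-channel continuous recordings.

Covers exactly what the pipeline needs: uniform-rate physical signals plus
an ``EDF Annotations`` channel carrying stimulus events as time-stamped
annotation lists (TALs).  16-bit quantization limits round-trip precision
to the physical range divided by 65535.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import StructuralError

__all__ = ["EdfRecording", "read_edf", "write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class EdfRecording:
    signals: np.ndarray  # (n_channels, n_samples), physical units
    sampling_rate: float
    channel_labels: list[str]
    annotations: list[tuple[float, str]]  # (onset seconds, text)


def _fit(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path,
    signals: np.ndarray,
    sampling_rate: float,
    channel_labels=None,
    annotations=None,
    physical_range: tuple[float, float] | None = None,
) -> Path:
    """Write a continuous EDF+C file with an annotations channel."""
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_total = signals.shape
    if channel_labels is None:
        channel_labels = [f"EEG ch{i + 1}" for i in range(n_ch)]
    annotations = sorted(annotations or [])
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("sampling_rate must be an integer number of Hz")
    n_records = max(1, math.ceil(n_total / fs))

    if physical_range is None:
        span = float(np.max(np.abs(signals))) if signals.size else 1.0
        span = max(span * 1.01, 1.0)
        physical_range = (-span, span)
    pmin, pmax = physical_range
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_total] = signals
    digital = np.clip(
        np.round((padded - pmin) / gain) + _DIG_MIN, _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    # per-record annotation byte streams (TAL format)
    rec_tals: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for onset, text in annotations:
            if r <= onset < r + 1:
                tal += f"+{onset:.6f}\x14{text}\x14\x00".encode("ascii")
        rec_tals.append(tal)
    ann_bytes = max(60, max(len(t) for t in rec_tals))
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_samples = ann_bytes // 2

    ns = n_ch + 1
    header = b"".join([
        _fit("0", 8),
        _fit("X X X X", 80),
        _fit("Startdate 01-JAN-2020 X X X", 80),
        _fit("01.01.20", 8),
        _fit("00.00.00", 8),
        _fit(str(256 * (ns + 1)), 8),
        _fit("EDF+C", 44),
        _fit(str(n_records), 8),
        _fit("1", 8),
        _fit(str(ns), 4),
    ])
    labels = list(channel_labels) + ["EDF Annotations"]
    n_samp = [fs] * n_ch + [ann_samples]
    pmins = [f"{pmin:.7g}"[:8]] * n_ch + ["-1"]
    pmaxs = [f"{pmax:.7g}"[:8]] * n_ch + ["1"]

    def field(values, width):
        return b"".join(_fit(str(v), width) for v in values)

    header += field(labels, 16)
    header += field([""] * ns, 80)  # transducer
    header += field(["uV"] * n_ch + [""], 8)  # physical dimension
    header += field(pmins, 8)
    header += field(pmaxs, 8)
    header += field([_DIG_MIN] * ns, 8)
    header += field([_DIG_MAX] * ns, 8)
    header += field([""] * ns, 80)  # prefiltering
    header += field(n_samp, 8)
    header += field([""] * ns, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ci in range(n_ch):
                fh.write(digital[ci, r * fs:(r + 1) * fs].tobytes())
            fh.write(rec_tals[r].ljust(ann_bytes, b"\x00"))
    return path


def read_edf(path) -> EdfRecording:
    """Read an EDF/EDF+C file with uniform-rate signals."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise StructuralError(f"{path}: truncated EDF header")

    def ascii_at(start, width):
        return raw[start:start + width].decode("ascii", "replace").strip()

    n_records = int(ascii_at(236, 8))
    record_duration = float(ascii_at(244, 8))
    ns = int(ascii_at(252, 4))

    # signal-field offsets within the per-signal header block:
    # label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8, dmax 8,
    # prefilter 80, n_samples 8, reserved 32
    offsets = {"label": 0, "dim": 96, "pmin": 104, "pmax": 112,
               "dmin": 120, "dmax": 128, "nsamp": 216}

    def block(name, width, conv):
        base = 256 + offsets[name] * ns
        return [conv(raw[base + i * width: base + (i + 1) * width]
                     .decode("ascii", "replace").strip()) for i in range(ns)]

    labels = block("label", 16, str)
    pmin = block("pmin", 8, float)
    pmax = block("pmax", 8, float)
    dmin = block("dmin", 8, float)
    dmax = block("dmax", 8, float)
    nsamp = block("nsamp", 8, int)

    data_start = 256 * (ns + 1)
    rec_len = sum(nsamp)  # int16 samples per record
    body = np.frombuffer(raw, dtype="<i2", offset=data_start)
    if body.size < n_records * rec_len:
        raise StructuralError(f"{path}: data shorter than header promises")
    body = body[: n_records * rec_len].reshape(n_records, rec_len)

    ann_idx = [i for i, lab in enumerate(labels) if lab == "EDF Annotations"]
    sig_idx = [i for i in range(ns) if i not in ann_idx]
    starts = np.concatenate([[0], np.cumsum(nsamp)])

    signals = []
    for i in sig_idx:
        dig = body[:, starts[i]:starts[i + 1]].reshape(-1).astype(float)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        signals.append((dig - dmin[i]) * gain + pmin[i])
    signals = np.stack(signals) if signals else np.empty((0, 0))

    annotations: list[tuple[float, str]] = []
    tal_re = re.compile(
        rb"([+-]\d+(?:\.\d+)?)(?:\x15[\d.]+)?\x14([^\x14\x00]*)\x14"
    )
    for i in ann_idx:
        stream = body[:, starts[i]:starts[i + 1]].tobytes()
        for m in tal_re.finditer(stream):
            text = m.group(2).decode("utf-8", "replace")
            if text:  # skip bare timekeeping TALs
                annotations.append((float(m.group(1)), text))
    annotations.sort()

    if sig_idx:
        fs_set = {nsamp[i] for i in sig_idx}
        if len(fs_set) != 1:
            raise StructuralError(f"{path}: non-uniform sampling across signals")
        fs = fs_set.pop() / record_duration
    else:
        fs = 0.0
    return EdfRecording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=[labels[i] for i in sig_idx],
        annotations=annotations,
    )
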