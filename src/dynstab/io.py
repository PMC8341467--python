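"""Multichannel recordings: data model, text I/O, filtering, and windowing.

A :class:`Recording` is a channels-by-samples matrix with a sampling rate,
unique channel labels, and optional event annotations (e.g. seizure onset
markers). Recordings round-trip through a plain CSV matrix plus a JSON
sidecar carrying the metadata, so that every artifact in the pipeline is
human-readable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Event",
    "Recording",
    "WindowIndex",
    "read_recording",
    "write_recording",
    "highpass",
    "slice_windows",
]


@dataclass(frozen=True)
class Event:
    """A labelled time marker, e.g. 'UEO' (unequivocal electrographic onset)."""

    label: str
    t_start: float
    t_end: float | None = None

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise ValueError(f"event {self.label!r}: t_start must be >= 0")
        if self.t_end is not None and self.t_end < self.t_start:
            raise ValueError(f"event {self.label!r}: t_end < t_start")


@dataclass
class Recording:
    """Channels x samples multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes (nominally microvolts); channels-first throughout.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str, optional
        Unique labels; defaults to ``ch01 ...``.
    events : list of Event, optional
    units : str
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None
    events: list[Event] = field(default_factory=list)
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        n, t = self.data.shape
        if t < 2:
            raise ValueError("recording must contain at least 2 samples")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains missing or non-finite values")
        if not (np.isscalar(self.fs) or np.ndim(self.fs) == 0) or not self.fs > 0:
            raise ValueError("sampling rate fs must be a positive scalar")
        self.fs = float(self.fs)
        if self.channel_labels is None:
            width = max(2, len(str(n)))
            self.channel_labels = [f"ch{i + 1:0{width}d}" for i in range(n)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n:
            raise ValueError("channel_labels length must match channel count")
        if len(set(self.channel_labels)) != n:
            raise ValueError("channel labels must be unique")
        for ev in self.events:
            if ev.t_start > self.duration or (
                ev.t_end is not None and ev.t_end > self.duration
            ):
                raise ValueError(f"event {ev.label!r} lies outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)

    def event_time(self, label: str) -> float:
        """Start time of the first event with the given label."""
        for ev in self.events:
            if ev.label == label:
                return ev.t_start
        raise KeyError(f"no event labelled {label!r}")


@dataclass(frozen=True)
class WindowIndex:
    """Half-open sample window [start, stop) with its center time in seconds."""

    start: int
    stop: int
    center_time: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValueError("require 0 <= start < stop")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a CSV matrix (one row per channel, first column
    the channel label) plus a JSON sidecar with fs, units, labels, events.

    Values are written at full double precision so the round trip through
    :func:`read_recording` is lossless.
    """
    path = Path(path)
    df = pd.DataFrame(rec.data, index=rec.channel_labels)
    df.to_csv(path, header=False, float_format="%.17g")
    meta: dict = {
        "fs": rec.fs,
        "units": rec.units,
        "channel_labels": rec.channel_labels,
    }
    if rec.events:
        meta["events"] = [
            {"label": ev.label, "t_start": ev.t_start, "t_end": ev.t_end}
            for ev in rec.events
        ]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    transposed: bool = False,
) -> Recording:
    """Read a Recording from disk.

    Parameters
    ----------
    path : path to the CSV matrix (or EDF file with ``format='edf'``).
    format : {'csv', 'edf'}
    fs : sampling rate override in Hz; required for CSV files without a
        JSON sidecar.
    transposed : if True, the CSV stores one column per channel with a
        header row of channel labels.
    """
    path = Path(path)
    if format == "edf":
        return _read_edf(path)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fs is None:
        fs = meta.get("fs")
    if fs is None or not fs > 0:
        raise ValueError("sampling rate missing or non-positive; pass fs=")

    if transposed:
        df = pd.read_csv(path)
        labels = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float).T
    else:
        df = pd.read_csv(path, header=None, index_col=0)
        labels = [str(c) for c in df.index]
        data = df.to_numpy(dtype=float)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in file")

    events = [
        Event(e["label"], float(e["t_start"]),
              None if e.get("t_end") is None else float(e["t_end"]))
        for e in meta.get("events", [])
    ]
    return Recording(
        data=data,
        fs=float(fs),
        channel_labels=meta.get("channel_labels", labels),
        events=events,
        units=meta.get("units", "uV"),
    )


def _read_edf(path: Path) -> Recording:
    """Optional European Data Format reader (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        units="V",
    )


def highpass(rec: Recording, cutoff_hz: float = 0.1, order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass filter.

    A forward-backward (``sosfiltfilt``) pass keeps event times aligned with
    the filtered signal; the default 0.1 Hz cutoff removes drift and DC while
    leaving physiological rhythms untouched.
    """
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def slice_windows(
    rec: Recording, window_s: float = 1.0, shift_s: float = 0.1
) -> list[WindowIndex]:
    """Sliding-window sample indices: half-open [start, stop) windows of
    round(window_s * fs) samples advanced by round(shift_s * fs) samples.

    The last window is the last one fully inside the recording.
    """
    if shift_s <= 0:
        raise ValueError("shift_s must be positive")
    w = int(round(window_s * rec.fs))
    s = int(round(shift_s * rec.fs))
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    if s < 1:
        raise ValueError("shift must be at least 1 sample")
    n = rec.n_samples
    if w > n:
        raise ValueError("window longer than recording")
    n_windows = (n - w) // s + 1
    return [
        WindowIndex(start=i * s, stop=i * s + w,
                    center_time=(2 * i * s + w) / (2 * rec.fs))
        for i in range(n_windows)
    ]
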