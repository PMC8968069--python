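"""Core in-memory containers shared across the pipeline.

A session is a continuous multichannel recording (channels x samples, in
microvolts) plus per-channel shaft/contact metadata and a table of stimulus
events.  Derived objects (band-power / ERP traces, trial epochs) keep the
same channel ordering and time base as their source recording.

Conventions: samples are 0-based, time intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "Recording",
    "EventTable",
    "TraceSet",
    "EpochSet",
    "GroundTruth",
    "IDLE",
    "ACTIVE",
    "OWN",
    "OTHER",
    "save_session",
    "load_session",
]

# State labels used throughout (integer codes index into transition matrices).
IDLE = "idle"
ACTIVE = "active"
OWN = "own"
OTHER = "other"


@dataclass(frozen=True)
class ChannelInfo:
    """One depth-electrode contact: a channel id, its shaft and its position
    (contact index) along the shaft."""

    id: str
    shaft: str
    contact: int


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts (or derived units after filtering).
    fs : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
        Shaft/contact metadata, one entry per row of ``data``.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata does not match data rows")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be a positive sampling rate in Hz")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_ids(self) -> list[str]:
        return [c.id for c in self.channels]

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(f"unknown channel id: {channel_id!r}")

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channels))


@dataclass
class EventTable:
    """Stimulus events: onset sample, stimulus type label, duration."""

    onset_sample: np.ndarray
    stim_type: np.ndarray
    duration_ms: np.ndarray

    def __post_init__(self) -> None:
        self.onset_sample = np.asarray(self.onset_sample, dtype=np.int64)
        self.stim_type = np.asarray(self.stim_type, dtype=object)
        self.duration_ms = np.asarray(self.duration_ms, dtype=np.float64)
        n = len(self.onset_sample)
        if len(self.stim_type) != n or len(self.duration_ms) != n:
            raise ValueError("event columns must have equal length")

    def __len__(self) -> int:
        return len(self.onset_sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": self.onset_sample,
                "type": self.stim_type,
                "duration_ms": self.duration_ms,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["onset_sample"].to_numpy(),
            df["type"].to_numpy(),
            df["duration_ms"].to_numpy(),
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "EventTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


TRACE_KINDS = ("high_gamma", "beta", "alpha", "erp")


@dataclass
class TraceSet:
    """Per-channel continuous traces of one kind (band power or ERP),
    aligned sample-for-sample with the source recording."""

    kind: str
    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def units(self) -> str:
        return "uV" if self.kind == "erp" else "uV^2"

    @property
    def channel_ids(self) -> list[str]:
        return [c.id for c in self.channels]


@dataclass
class EpochSet:
    """Trial epochs of one trace kind.

    ``data`` has shape (n_channels, n_trials, n_samples); the epoch covers
    ``window_ms`` relative to stimulus onset, with ``baseline_ms`` used for
    per-trial z-scoring.
    """

    kind: str
    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    normalized: bool = False
    trial_types: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def time_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + 1000.0 * np.arange(n) / self.fs

    def sample_slice(self, span_ms: tuple[float, float]) -> slice:
        """Samples of the epoch falling in ``[span_ms[0], span_ms[1])``."""
        start = int(round((span_ms[0] - self.window_ms[0]) * self.fs / 1000.0))
        stop = int(round((span_ms[1] - self.window_ms[0]) * self.fs / 1000.0))
        return slice(max(start, 0), stop)


@dataclass
class GroundTruth:
    """Per-sample state timeline plus the set of planted responsive channels.

    ``timeline`` holds one state label per sample.  The active span of each
    stimulus is ``[onset + 300 ms, onset + 1000 ms)``.
    """

    timeline: np.ndarray  # (n_samples,), object dtype of state labels
    fs: float
    responsive: dict[str, list[str]] = field(default_factory=dict)

    def state_at(self, sample: int) -> str:
        return self.timeline[sample]

    def active_periods(self, collapse: bool = True) -> list[tuple[float, float]]:
        """Contiguous non-idle spans in seconds (half-open intervals)."""
        labels, starts, ends = _runs(self.timeline)
        out = []
        for lab, s, e in zip(labels, starts, ends):
            if lab != IDLE:
                out.append((s / self.fs, e / self.fs))
        if not collapse:
            return out
        return out

    def labeled_periods(self) -> list[tuple[str, float, float]]:
        """All contiguous runs as (state, start_s, end_s)."""
        labels, starts, ends = _runs(self.timeline)
        return [(l, s / self.fs, e / self.fs) for l, s, e in zip(labels, starts, ends)]


def _runs(seq: np.ndarray) -> tuple[list, np.ndarray, np.ndarray]:
    """Maximal runs of equal values: (values, start indices, end indices)."""
    n = len(seq)
    if n == 0:
        return [], np.array([], int), np.array([], int)
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [seq[s] for s in starts], starts, ends


# ---------------------------------------------------------------------------
# Session container I/O: compressed array file + tab-separated sidecars.

def save_session(
    directory: str,
    rec: Recording,
    events: EventTable,
    truth: GroundTruth | None = None,
) -> None:
    """Write a session: ``signal.npz`` (data, fs, optional truth timeline),
    ``channels.tsv`` (id, shaft, contact) and ``events.tsv``."""
    os.makedirs(directory, exist_ok=True)
    arrays = {"data": rec.data, "fs": np.float64(rec.fs)}
    if truth is not None:
        arrays["timeline"] = truth.timeline.astype("U16")
    np.savez_compressed(os.path.join(directory, "signal.npz"), **arrays)
    pd.DataFrame(
        {
            "id": [c.id for c in rec.channels],
            "shaft": [c.shaft for c in rec.channels],
            "contact": [c.contact for c in rec.channels],
        }
    ).to_csv(os.path.join(directory, "channels.tsv"), sep="\t", index=False)
    events.to_tsv(os.path.join(directory, "events.tsv"))


def load_session(directory: str) -> tuple[Recording, EventTable, GroundTruth | None]:
    with np.load(os.path.join(directory, "signal.npz"), allow_pickle=False) as z:
        data = z["data"]
        fs = float(z["fs"])
        timeline = z["timeline"].astype(object) if "timeline" in z else None
    ch = pd.read_csv(os.path.join(directory, "channels.tsv"), sep="\t")
    channels = [
        ChannelInfo(str(r.id), str(r.shaft), int(r.contact)) for r in ch.itertuples()
    ]
    rec = Recording(data, fs, channels)
    events = EventTable.from_tsv(os.path.join(directory, "events.tsv"))
    truth = GroundTruth(timeline, fs) if timeline is not None else None
    return rec, events, truth
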