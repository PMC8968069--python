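"""From raw recordings to the four per-channel signal traces.

Power traces (high-gamma 60-140 Hz, beta 13-30 Hz, alpha 8-12 Hz) follow the
fixed order: 50 Hz comb notch -> Laplacian re-reference -> Butterworth
band-pass -> Hilbert transform -> squared magnitude.  The ERP trace follows:
comb notch -> 0.5 Hz high-pass -> Laplacian re-reference.

All filters are applied zero-phase (forward-backward) by default so that the
300-1000 ms post-onset active window stays aligned across bands; causal
single-pass filtering is available via ``zero_phase=False``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from .containers import ChannelInfo, EpochSet, EventTable, Recording, TraceSet

__all__ = [
    "BANDS",
    "recording_from_mne_raw",
    "load_edf",
    "comb_notch",
    "highpass",
    "bandpass",
    "laplacian_rereference",
    "hilbert_power",
    "band_power_trace",
    "erp_trace",
    "compute_traces",
    "epoch_and_normalize",
    "gaussian_smooth",
]

BANDS = {"high_gamma": (60.0, 140.0), "beta": (13.0, 30.0), "alpha": (8.0, 12.0)}


def recording_from_mne_raw(raw) -> Recording:
    """Build a Recording from an MNE ``Raw`` object (data in volts are
    converted to microvolts).

    Shaft/contact metadata is parsed from channel names of the usual SEEG
    form ``<shaft letters><contact number>`` (e.g. ``A1``, ``B12``,
    optionally with a modality prefix like ``EEG A1``).
    """
    import re

    data = raw.get_data() * 1e6
    channels = []
    for name in raw.ch_names:
        m = re.search(r"([A-Za-z']+)\s*(\d+)\s*$", name)
        if not m:
            raise ValueError(f"cannot parse shaft/contact from channel {name!r}")
        channels.append(ChannelInfo(name, m.group(1), int(m.group(2))))
    return Recording(data, float(raw.info["sfreq"]), channels)


def load_edf(path: str) -> Recording:
    """Read a continuous EDF recording (requires mne)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return recording_from_mne_raw(raw)


def _apply_sos(sos: np.ndarray, data: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def comb_notch(
    rec: Recording, base_hz: float = 50.0, q: float = 35.0, zero_phase: bool = True
) -> Recording:
    """Remove line noise and its harmonics.

    Cascaded second-order IIR notches at ``base_hz, 2*base_hz, ...`` up to
    Nyquist, each with quality factor ``q`` (narrow stopbands, <1 dB ripple
    away from the notches).
    """
    if base_hz >= rec.fs / 2:
        raise ValueError("notch base frequency must be below Nyquist")
    sections = []
    f = base_hz
    while f < rec.fs / 2:
        b, a = signal.iirnotch(f, q, fs=rec.fs)
        sections.append(np.hstack([b, a]))
        f += base_hz
    sos = np.array(sections)
    return Recording(_apply_sos(sos, rec.data, zero_phase), rec.fs, list(rec.channels))


def highpass(
    rec: Recording, cutoff_hz: float = 0.5, order: int = 2, zero_phase: bool = True
) -> Recording:
    """Butterworth high-pass (drift / DC removal ahead of the ERP trace)."""
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError("cutoff must lie inside (0, Nyquist)")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    return Recording(_apply_sos(sos, rec.data, zero_phase), rec.fs, list(rec.channels))


def bandpass(
    rec: Recording,
    band: tuple[float, float],
    order: int = 6,
    zero_phase: bool = True,
) -> Recording:
    """Butterworth band-pass of the stated overall ``order`` (must be even:
    a band-pass of order 2N is designed from an order-N prototype)."""
    low, high = band
    if not (0 < low < high < rec.fs / 2):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = signal.butter(order // 2, band, btype="bandpass", fs=rec.fs, output="sos")
    return Recording(_apply_sos(sos, rec.data, zero_phase), rec.fs, list(rec.channels))


def shaft_laplacian_matrix(n_contacts: int) -> np.ndarray:
    """Matrix form of the per-shaft Laplacian reference: interior contacts
    subtract the mean of their two neighbours, shaft ends subtract their
    single neighbour (bipolar fallback)."""
    if n_contacts < 2:
        raise ValueError("a shaft needs at least 2 contacts")
    L = np.eye(n_contacts)
    L[0, 1] = -1.0
    L[-1, -2] = -1.0
    for i in range(1, n_contacts - 1):
        L[i, i - 1] = L[i, i + 1] = -0.5
    return L


def laplacian_rereference(rec: Recording) -> Recording:
    """Subtract from each contact the mean of its two shaft-adjacent contacts.

    Shaft-end contacts fall back to a bipolar reference against their single
    neighbour; a shaft with one contact is dropped with a warning.
    """
    by_shaft: dict[str, list[int]] = {}
    for i, c in enumerate(rec.channels):
        by_shaft.setdefault(c.shaft, []).append(i)
    keep: list[int] = []
    new = np.empty_like(rec.data)
    for shaft, idx in by_shaft.items():
        idx = sorted(idx, key=lambda i: rec.channels[i].contact)
        if len(idx) < 2:
            warnings.warn(
                f"shaft {shaft!r} has a single contact; channel dropped",
                stacklevel=2,
            )
            continue
        for k, i in enumerate(idx):
            if k == 0:
                ref = rec.data[idx[1]]
            elif k == len(idx) - 1:
                ref = rec.data[idx[-2]]
            else:
                ref = 0.5 * (rec.data[idx[k - 1]] + rec.data[idx[k + 1]])
            new[i] = rec.data[i] - ref
            keep.append(i)
    keep = sorted(keep)
    return Recording(new[keep], rec.fs, [rec.channels[i] for i in keep])


def hilbert_power(rec: Recording, kind: str = "high_gamma") -> TraceSet:
    """Squared magnitude of the analytic signal (band power trace).

    The input must already be band-passed; the output is non-negative and
    sample-aligned with the input.
    """
    analytic = signal.hilbert(rec.data, axis=-1)
    return TraceSet(kind, np.abs(analytic) ** 2, rec.fs, list(rec.channels))


def band_power_trace(
    rec: Recording, kind: str, zero_phase: bool = True, notched: Recording | None = None
) -> TraceSet:
    """Full power pipeline for one band: notch -> Laplacian -> band-pass ->
    Hilbert -> square.  Pass ``notched`` to reuse an already notch-filtered
    recording."""
    x = notched if notched is not None else comb_notch(rec, zero_phase=zero_phase)
    x = laplacian_rereference(x)
    x = bandpass(x, BANDS[kind], zero_phase=zero_phase)
    return hilbert_power(x, kind)


def erp_trace(
    rec: Recording, zero_phase: bool = True, notched: Recording | None = None
) -> TraceSet:
    """ERP pipeline: notch -> 0.5 Hz high-pass -> Laplacian re-reference."""
    x = notched if notched is not None else comb_notch(rec, zero_phase=zero_phase)
    x = highpass(x, 0.5, zero_phase=zero_phase)
    x = laplacian_rereference(x)
    return TraceSet("erp", x.data, x.fs, list(x.channels))


def compute_traces(rec: Recording, zero_phase: bool = True) -> dict[str, TraceSet]:
    """All four traces, sharing a single notch-filtered intermediate."""
    notched = comb_notch(rec, zero_phase=zero_phase)
    traces = {
        kind: band_power_trace(rec, kind, zero_phase=zero_phase, notched=notched)
        for kind in BANDS
    }
    traces["erp"] = erp_trace(rec, zero_phase=zero_phase, notched=notched)
    return traces


def epoch_and_normalize(
    trace: TraceSet,
    events: EventTable,
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    normalize: bool = True,
    mode: str = "per_trial",
) -> EpochSet:
    """Cut the continuous trace into stimulus-locked trials and z-score
    against the pre-stimulus baseline.

    ``mode='per_trial'`` z-scores each trial against its own baseline (the
    per-trial baseline then has mean 0 / SD 1 exactly).  ``mode='pooled'``
    z-scores every trial of a channel with the baseline statistics pooled
    over all its trials; this keeps the baseline means informative, which the
    label-permutation channel statistic needs (with per-trial scoring every
    idle mean is identically zero and the shuffled-label null is no longer
    exchangeable).

    Trials whose epoch window exceeds the recording bounds are dropped with a
    warning; a zero baseline standard deviation raises.
    """
    fs = trace.fs
    s0 = int(round(window_ms[0] * fs / 1000.0))
    s1 = int(round(window_ms[1] * fs / 1000.0))
    n_ep = s1 - s0
    n = trace.data.shape[1]
    keep, arrs = [], []
    for i, onset in enumerate(events.onset_sample):
        a, b = onset + s0, onset + s1
        if a < 0 or b > n:
            warnings.warn(f"trial {i} epoch exceeds recording bounds; dropped",
                          stacklevel=2)
            continue
        keep.append(i)
        arrs.append(trace.data[:, a:b])
    if not arrs:
        raise ValueError("no trial fits inside the recording")
    data = np.stack(arrs, axis=1)  # channels x trials x time
    ep = EpochSet(
        trace.kind,
        data,
        fs,
        list(trace.channels),
        window_ms=window_ms,
        baseline_ms=baseline_ms,
        trial_types=events.stim_type[keep],
    )
    if normalize:
        sl = ep.sample_slice(baseline_ms)
        base = data[:, :, sl]
        if mode == "per_trial":
            mu = base.mean(axis=2, keepdims=True)
            sd = base.std(axis=2, keepdims=True)
        elif mode == "pooled":
            mu = base.mean(axis=(1, 2), keepdims=True)
            sd = base.std(axis=(1, 2), keepdims=True)
        else:
            raise ValueError("mode must be 'per_trial' or 'pooled'")
        if np.any(sd == 0):
            raise ValueError("zero baseline standard deviation; cannot z-score")
        ep.data = (data - mu) / sd
        ep.normalized = True
    return ep


def gaussian_kernel(width_ms: float, fs: float) -> np.ndarray:
    """Unit-area Gaussian of total support ``width_ms`` with sigma=support/6
    (conventional +/-3 sigma truncation)."""
    n = max(int(round(width_ms * fs / 1000.0)), 1)
    sigma = n / 6.0
    k = signal.windows.gaussian(n, sigma)
    return k / k.sum()


def gaussian_smooth(epochs: EpochSet, width_ms: float = 80.0) -> EpochSet:
    """Convolve each trial with an 80-ms unit-area Gaussian window.

    Length is preserved using reflect padding at the epoch edges.
    """
    k = gaussian_kernel(width_ms, epochs.fs)
    n = epochs.data.shape[-1]
    if len(k) >= n:
        raise ValueError("smoothing kernel must be shorter than the epoch")
    sm = ndimage.convolve1d(epochs.data, k, axis=-1, mode="reflect")
    return EpochSet(
        epochs.kind,
        sm,
        epochs.fs,
        list(epochs.channels),
        window_ms=epochs.window_ms,
        baseline_ms=epochs.baseline_ms,
        normalized=epochs.normalized,
        trial_types=epochs.trial_types,
    )
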