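"""Ground-truthed synthetic SEEG sessions.

Emulates an intermittent auditory-name paradigm: a pseudo-random sequence of
two stimulus types (own / other name), 1-2 s stimuli separated by 1-2 s
inter-trial intervals with optional jitter, recorded on depth-electrode
shafts.  The background is 1/f-shaped noise plus 50 Hz line interference and
white sensor noise.  A chosen subset of channels receives evoked responses:

* high-gamma (or beta/alpha) responses are a *multiplicative* envelope on
  band-limited noise added during the response window, so the Hilbert power
  of the response scales with the square of the gain;
* ERP responses are a fixed-polarity sum of damped low-frequency (<15 Hz)
  sinusoids, giving amplitude and line-length features signal to find.

The ground-truth state timeline marks ``[onset + 300 ms, onset + 1000 ms)``
after every stimulus as the active state (labelled by stimulus type), and
everything else as idle.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import (
    ACTIVE,
    IDLE,
    OTHER,
    OWN,
    ChannelInfo,
    EventTable,
    GroundTruth,
    Recording,
)

__all__ = [
    "ParadigmConfig",
    "ResponseProfile",
    "build_event_schedule",
    "generate_background",
    "inject_responses",
    "default_paradigm",
    "default_profiles",
    "simulate_session",
]

BANDS = {"high_gamma": (60.0, 140.0), "beta": (13.0, 30.0), "alpha": (8.0, 12.0)}

# Active-state window relative to stimulus onset (ms).
ACTIVE_WINDOW_MS = (300.0, 1000.0)


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing and composition of one stimulation session.

    ``iti_ms`` may be a single duration or a ``(low, high)`` range from which
    each trial's inter-trial interval is drawn uniformly (jitter).
    ``stim_types`` maps type labels to their proportions (must sum to 1);
    trials are split in equal counts (+/-1) and pseudo-randomly ordered.
    """

    n_trials: int = 120
    stim_duration_ms: float = 1000.0
    iti_ms: float | tuple[float, float] = (1100.0, 1300.0)
    cue_ms: float = 100.0
    prep_ms: float = 500.0
    stim_types: dict[str, float] = field(
        default_factory=lambda: {OWN: 0.5, OTHER: 0.5}
    )
    fs: float = 1000.0
    lead_in_ms: float = 2000.0

    def iti_range(self) -> tuple[float, float]:
        if np.isscalar(self.iti_ms):
            return (float(self.iti_ms), float(self.iti_ms))
        lo, hi = self.iti_ms  # type: ignore[misc]
        return (float(lo), float(hi))

    def validate(self) -> None:
        lo, hi = self.iti_range()
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.stim_duration_ms <= 0:
            raise ValueError("stim_duration_ms must be positive")
        if lo > hi or lo < 0:
            raise ValueError("iti range must satisfy 0 <= low <= high")
        if self.cue_ms < 0 or self.prep_ms < 0 or self.lead_in_ms < 0:
            raise ValueError("durations must be non-negative")
        if self.fs < 500:
            raise ValueError("fs must be at least 500 Hz")
        props = np.array(list(self.stim_types.values()), float)
        if len(props) == 0 or not np.isclose(props.sum(), 1.0):
            raise ValueError("stim type proportions must sum to 1")


@dataclass(frozen=True)
class ResponseProfile:
    """Planted evoked response on one channel.

    ``gain`` is a unitless multiplier on the channel's baseline envelope in
    the profile's band (for ERP: on the baseline low-frequency amplitude);
    ``type_gain`` optionally rescales the gain per stimulus type.
    """

    channel: str
    kind: str = "high_gamma"  # high_gamma | beta | alpha | erp
    latency_ms: float = 300.0
    duration_ms: float = 700.0
    gain: float = 3.0
    type_gain: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in (*BANDS, "erp"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        if self.gain < 0 or any(g < 0 for g in self.type_gain.values()):
            raise ValueError("gains must be >= 0")


def build_event_schedule(cfg: ParadigmConfig, seed: int) -> EventTable:
    """Lay out the trial sequence of a session.

    Each trial is cue -> preparation -> stimulus -> inter-trial interval, so
    consecutive onsets are separated by ``cue + prep + stim + iti`` where the
    ITI is drawn uniformly from the configured range.  Stimulus types appear
    in equal counts (+/-1 for odd splits) in a seeded pseudo-random order.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    types = list(cfg.stim_types)
    props = np.array([cfg.stim_types[t] for t in types], float)
    # largest-remainder apportionment of n_trials to the type proportions
    raw = props * cfg.n_trials
    counts = np.floor(raw).astype(int)
    rem = cfg.n_trials - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    seq = np.repeat(np.array(types, object), counts)
    rng.shuffle(seq)

    lo, hi = cfg.iti_range()
    itis = rng.uniform(lo, hi, size=cfg.n_trials)
    fs = cfg.fs
    onsets = np.empty(cfg.n_trials, dtype=np.int64)
    t_ms = cfg.lead_in_ms
    for i in range(cfg.n_trials):
        t_ms += cfg.cue_ms + cfg.prep_ms
        onsets[i] = int(round(t_ms * fs / 1000.0))
        t_ms += cfg.stim_duration_ms + itis[i]
    durations = np.full(cfg.n_trials, cfg.stim_duration_ms)
    return EventTable(onsets, seq, durations)


def session_length_samples(cfg: ParadigmConfig, events: EventTable) -> int:
    """Samples needed to hold the schedule plus a trailing lead-out equal to
    the lead-in."""
    last = int(events.onset_sample[-1])
    tail_ms = cfg.stim_duration_ms + cfg.iti_range()[1] + cfg.lead_in_ms
    return last + int(round(tail_ms * cfg.fs / 1000.0))


def _shaft_layout(n_channels: int, shaft_size: int) -> list[ChannelInfo]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n_channels):
        s, c = divmod(i, shaft_size)
        prefix = letters[s % 26] * (s // 26 + 1)
        out.append(ChannelInfo(f"{prefix}{c + 1}", prefix, c + 1))
    return out


def generate_background(
    n_channels: int,
    duration_s: float,
    fs: float,
    line_amp: float = 5.0,
    seed: int = 0,
    pink_rms: float = 10.0,
    white_rms: float = 2.0,
    shaft_size: int = 10,
) -> Recording:
    """Background recording: per-channel 1/f-shaped noise (RMS ``pink_rms``
    microvolts) + ``line_amp * sin(2 pi 50 t)`` line interference + white
    sensor noise.  Channels are laid out on shafts of ``shaft_size`` contacts.
    """
    if fs < 500:
        raise ValueError("fs must be at least 500 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # 1/f amplitude shaping, flattened below 1 Hz to keep variance finite
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shape[0] = 0.0
    t = np.arange(n) / fs
    line = line_amp * np.sin(2 * np.pi * 50.0 * t)
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        white = rng.standard_normal(n)
        pink = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        pink *= pink_rms / np.std(pink)
        data[ch] = pink + line + white_rms * rng.standard_normal(n)
    return Recording(data, fs, _shaft_layout(n_channels, shaft_size))


def _response_envelope(n_resp: int, fs: float) -> np.ndarray:
    """Smooth plateau envelope (Tukey, 25% taper) over the response span."""
    return signal.windows.tukey(n_resp, alpha=0.25)


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
    return float(np.std(signal.sosfiltfilt(sos, x)))


def _erp_waveform(n: int, fs: float) -> np.ndarray:
    """Fixed-polarity evoked potential: a slow monophasic deflection (which
    gives the window a non-zero mean amplitude) plus damped sinusoids below
    15 Hz (which give line-length something to demodulate); unit peak."""
    tau = np.arange(n) / fs
    w = (
        1.2 * np.exp(-0.5 * ((tau - 0.22) / 0.12) ** 2)
        + 1.0 * np.sin(2 * np.pi * 4.0 * tau) * np.exp(-tau / 0.25)
        + 0.6 * np.sin(2 * np.pi * 7.0 * tau) * np.exp(-tau / 0.15)
        + 0.4 * np.sin(2 * np.pi * 12.0 * tau) * np.exp(-tau / 0.10)
    )
    peak = np.max(np.abs(w))
    return w / peak if peak > 0 else w


def _source_weights(
    rec: Recording, channel_index: int, spatial: str
) -> list[tuple[int, float]]:
    """Spatial injection pattern for one source channel.

    ``focal`` puts the response on the named channel only.  ``spread``
    distributes it over the channel's shaft with the least-squares preimage
    of the shaft Laplacian, emulating a volume-conducted source that the
    Laplacian reference focalizes back onto the named contact.
    """
    if spatial == "focal":
        return [(channel_index, 1.0)]
    if spatial != "spread":
        raise ValueError("spatial must be 'focal' or 'spread'")
    from .preprocessing import shaft_laplacian_matrix

    shaft = rec.channels[channel_index].shaft
    members = [i for i, c in enumerate(rec.channels) if c.shaft == shaft]
    members.sort(key=lambda i: rec.channels[i].contact)
    if len(members) < 2:
        return [(channel_index, 1.0)]
    L = shaft_laplacian_matrix(len(members))
    e = np.zeros(len(members))
    e[members.index(channel_index)] = 1.0
    w, *_ = np.linalg.lstsq(L, e, rcond=None)
    return [(i, float(wi)) for i, wi in zip(members, w) if abs(wi) > 1e-12]


def inject_responses(
    rec: Recording,
    events: EventTable,
    profiles: list[ResponseProfile],
    seed: int = 0,
    spatial: str = "focal",
) -> tuple[Recording, GroundTruth]:
    """Plant evoked responses and return the modified recording plus the
    ground-truth state timeline.

    With ``spatial='focal'`` only channels named by a profile are touched;
    ``spatial='spread'`` additionally writes the Laplacian-compensated
    source pattern onto the rest of the shaft so that after re-referencing
    the response appears on the named contact alone.  A profile with an
    effective gain of zero leaves the signal bit-identical.  The timeline
    labels ``[onset + 300, onset + 1000) ms`` of every stimulus with its
    stimulus type and everything else idle.
    """
    for p in profiles:
        p.validate()
        rec.channel_index(p.channel)  # raises KeyError on unknown channel

    rng = np.random.default_rng(seed)
    out = rec.copy()
    fs = rec.fs
    n = rec.n_samples

    timeline = np.full(n, IDLE, dtype=object)
    a0 = int(round(ACTIVE_WINDOW_MS[0] * fs / 1000.0))
    a1 = int(round(ACTIVE_WINDOW_MS[1] * fs / 1000.0))
    for onset, stype in zip(events.onset_sample, events.stim_type):
        timeline[onset + a0 : min(onset + a1, n)] = stype

    responsive: dict[str, list[str]] = {}
    for p in profiles:
        ci = rec.channel_index(p.channel)
        gains = np.array(
            [p.gain * p.type_gain.get(t, 1.0) for t in events.stim_type]
        )
        if np.all(gains == 0):
            continue
        responsive.setdefault(p.kind, []).append(p.channel)
        weights = _source_weights(rec, ci, spatial)
        n_resp = int(round(p.duration_ms * fs / 1000.0))
        lat = int(round(p.latency_ms * fs / 1000.0))
        env = _response_envelope(n_resp, fs)
        # build the response component once, then write it with the spatial
        # pattern onto the shaft
        component = np.zeros(n)
        if p.kind == "erp":
            base = _band_rms(rec.data[ci], fs, (1.0, 15.0))
            wave = _erp_waveform(n_resp, fs) * env
            for onset, g in zip(events.onset_sample, gains):
                if g == 0:
                    continue
                s = onset + lat
                e = min(s + n_resp, n)
                component[s:e] += g * base * wave[: e - s]
        else:
            band = BANDS[p.kind]
            base = _band_rms(rec.data[ci], fs, band)
            sos = signal.butter(3, band, btype="bandpass", fs=fs, output="sos")
            carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
            carrier /= np.std(carrier)
            for onset, g in zip(events.onset_sample, gains):
                if g == 0:
                    continue
                s = onset + lat
                e = min(s + n_resp, n)
                component[s:e] += g * base * env[: e - s] * carrier[s:e]
        for idx, w in weights:
            out.data[idx] += w * component
    truth = GroundTruth(timeline, fs, responsive)
    return out, truth


def default_paradigm(**overrides) -> ParadigmConfig:
    """Session layout used throughout: 120 trials, 1 s stimuli, jittered
    1.1-1.3 s inter-trial intervals, 100 ms cue + 500 ms preparation, 1 kHz."""
    return ParadigmConfig(**overrides)


def default_profiles(
    channels: list[str] | None = None,
    gain: float = 3.0,
    erp_gain: float | None = None,
    type_gain: dict[str, float] | None = None,
) -> list[ResponseProfile]:
    """Default planted responses: five responsive channels out of the 20-channel
    two-shaft layout, spaced so Laplacian re-referencing does not cancel them.
    Each responsive channel carries a high-gamma response and an ERP response.
    """
    if channels is None:
        channels = ["A2", "A5", "A8", "B3", "B7"]
    tg = type_gain or {}
    profiles = []
    for ch in channels:
        profiles.append(
            ResponseProfile(ch, "high_gamma", gain=gain, type_gain=tg)
        )
        profiles.append(
            ResponseProfile(
                ch, "erp", gain=erp_gain if erp_gain is not None else gain,
                type_gain=tg,
            )
        )
    return profiles


def simulate_session(
    cfg: ParadigmConfig | None = None,
    profiles: list[ResponseProfile] | None = None,
    n_channels: int = 20,
    seed: int = 0,
    line_amp: float = 5.0,
    spatial: str = "spread",
    shaft_size: int = 10,
) -> tuple[Recording, EventTable, GroundTruth]:
    """Generate a complete session: schedule, background, planted responses
    (spread over the shaft by default so the Laplacian reference focalizes
    each response onto its planted contact)."""
    cfg = cfg or default_paradigm()
    rng = np.random.default_rng(seed)
    s_sched, s_bg, s_resp = rng.integers(0, 2**31 - 1, size=3)
    events = build_event_schedule(cfg, int(s_sched))
    n = session_length_samples(cfg, events)
    rec = generate_background(
        n_channels, n / cfg.fs, cfg.fs, line_amp=line_amp, seed=int(s_bg),
        shaft_size=shaft_size,
    )
    if profiles is None:
        profiles = default_profiles()
    rec, truth = inject_responses(
        rec, events, profiles, seed=int(s_resp), spatial=spatial
    )
    return rec, events, truth
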