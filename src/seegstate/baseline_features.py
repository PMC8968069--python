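"""Comparator feature extractors: AR spectral amplitude, short-time Fourier
band power, and analytic Morse-wavelet band power.

These operate on the re-referenced broadband signal (notch + Laplacian), one
value per sliding window per frequency band:

* ``ar_band_amplitude`` -- Yule-Walker autoregressive spectrum of order 100,
  evaluated on 1 Hz bins inside the band; the square roots of the PSD values
  ("spectral amplitudes") are averaged across bins.
* ``stft_band_power`` -- Hamming-windowed periodograms of sections of length
  floor(n/4.5) with 50% overlap; PSD averaged over band bins and sections.
* ``wavelet_band_power`` -- continuous wavelet transform with the analytic
  Morse wavelet (symmetry parameter gamma = 3, time-bandwidth product
  P^2 = 60, i.e. beta = P^2/gamma = 20), implemented from its frequency-
  domain definition; mean absolute coefficient over band scales and time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.regression.linear_model import yule_walker

from .features import WindowFeatureMatrix, WindowSpec, label_windows
from .containers import GroundTruth, Recording

__all__ = [
    "ar_band_amplitude",
    "stft_band_power",
    "wavelet_band_power",
    "morse_cwt",
    "extract_baseline_features",
]

BANDS = {"high_gamma": (60.0, 140.0), "beta": (13.0, 30.0), "alpha": (8.0, 12.0)}


def _band_bins(band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    bins = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    if len(bins) == 0:
        raise ValueError(f"no 1 Hz bin inside band {band}")
    return bins


def ar_band_amplitude(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 100,
    scale: str = "amplitude",
) -> float:
    """Mean AR spectral amplitude over 1 Hz bins inside ``band``.

    ``scale='amplitude'`` (default) averages sqrt(PSD); ``scale='psd'``
    averages the PSD itself.
    """
    x = np.asarray(x, float)
    if len(x) <= order:
        raise ValueError(f"window length {len(x)} must exceed AR order {order}")
    rho, sigma = yule_walker(x, order=order, method="mle")
    freqs = _band_bins(band)
    # PSD of AR process: sigma^2 / |1 - sum a_k e^{-i 2 pi f k / fs}|^2,
    # one-sided density scaling (x2 / fs) as in standard periodogram units
    k = np.arange(1, order + 1)
    E = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 - E @ rho) ** 2
    psd = 2.0 * sigma**2 / (fs * denom)
    if scale == "amplitude":
        return float(np.mean(np.sqrt(psd)))
    if scale == "psd":
        return float(np.mean(psd))
    raise ValueError("scale must be 'amplitude' or 'psd'")


def stft_band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean short-time PSD over the band (Hamming sections of length
    floor(n/4.5), 50% overlap, averaged over sections and band bins)."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 9:
        raise ValueError("window must hold at least 9 samples")
    nperseg = int(n / 4.5)
    f, psd = signal.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False,
    )
    mask = (f >= band[0]) & (f <= band[1])
    if not np.any(mask):
        raise ValueError(f"band {band} empty at resolution {f[1] - f[0]:.2f} Hz")
    return float(np.mean(psd[mask]))


def morse_cwt(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    gamma: float = 3.0,
    beta: float = 20.0,
) -> np.ndarray:
    """Continuous wavelet transform with the analytic generalized Morse
    wavelet, computed in the frequency domain.

    The wavelet is ``Psi(w) = 2 * U(w) * (w/wp)^beta * exp(wp^gamma - w^gamma)``
    with peak (angular) frequency ``wp = (beta/gamma)^(1/gamma)``; the scale
    for a target centre frequency aligns ``wp`` with it.  Returns complex
    coefficients of shape (len(freqs), len(x)).
    """
    x = np.asarray(x, float)
    n = len(x)
    X = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n, 1.0 / fs)
    wp = (beta / gamma) ** (1.0 / gamma)
    out = np.empty((len(freqs), n), dtype=complex)
    log_norm = beta * np.log(wp) - wp**gamma
    for i, fc in enumerate(freqs):
        s = wp / (2 * np.pi * fc)
        w = s * omega
        Psi = np.zeros(n)
        pos = w > 0
        Psi[pos] = 2.0 * np.exp(beta * np.log(w[pos]) - w[pos] ** gamma - log_norm)
        out[i] = np.fft.ifft(X * Psi)
    return out


def wavelet_band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    gamma: float = 3.0,
    time_bandwidth: float = 60.0,
) -> float:
    """Mean absolute Morse-wavelet coefficient over band scales and time."""
    x = np.asarray(x, float)
    if len(x) < 32:
        raise ValueError("window must hold at least 32 samples")
    beta = time_bandwidth / gamma
    freqs = _band_bins(band)
    W = morse_cwt(x, fs, freqs, gamma=gamma, beta=beta)
    return float(np.mean(np.abs(W)))


_EXTRACTORS = {
    "ar": lambda x, fs, band: ar_band_amplitude(x, fs, band),
    "stft": stft_band_power,
    "wavelet": wavelet_band_power,
}


def extract_baseline_features(
    rereferenced: Recording,
    selections: dict[str, list[str]],
    starts: np.ndarray,
    spec: WindowSpec,
    method: str,
    bands: list[str] | None = None,
    truth: GroundTruth | None = None,
    label_rule: str = "midpoint",
    binary_labels: bool = True,
) -> WindowFeatureMatrix:
    """Window x feature matrix of one comparator extractor.

    Each band contributes one column per channel of *its own* selected
    channel set (column name ``<band>:<channel>:<method>``).
    """
    if method not in _EXTRACTORS:
        raise ValueError(f"method must be one of {sorted(_EXTRACTORS)}")
    fn = _EXTRACTORS[method]
    fs = rereferenced.fs
    length = spec.length_samples(fs)
    cols: dict[str, np.ndarray] = {}
    for band_name in bands or list(BANDS):
        chans = selections.get(band_name, [])
        for ch in sorted(chans):
            row = rereferenced.data[rereferenced.channel_index(ch)]
            vals = np.array(
                [fn(row[s : s + length], fs, BANDS[band_name]) for s in starts]
            )
            cols[f"{band_name}:{ch}:{method}"] = vals
    if not cols:
        raise ValueError("no selected channel in any band")
    labels = (
        label_windows(starts, length, truth, rule=label_rule, binary=binary_labels)
        if truth is not None
        else np.full(len(starts), "", dtype=object)
    )
    return WindowFeatureMatrix(
        pd.DataFrame(cols), labels, starts / fs, (starts + length) / fs
    )
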