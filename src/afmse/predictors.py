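"""Classic f-wave predictors: FWA, nFWA, dominant frequency, fundamental.

FWA is the root-mean-square amplitude of the f-waves f(n) in mV; nFWA
normalizes it by the RMS of the preprocessed ECG evaluated at the R-peak
samples, reducing inter-patient attenuation effects (chest wall, skin
impedance).  The dominant frequency (DF) is the location of the largest
peak of the Welch power spectral density within 3-12 Hz, after discarding
windows whose spectrum correlates poorly with the rest (noise / QRST
residua screening).  The fundamental component ff(n) is the f-wave signal
band-passed around the DF with a zero-phase 9th-order Chebyshev type II
filter (5 Hz band, 20 dB stopband attenuation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal as sps

from .preprocess import FilterSpec, zero_phase_filter
from .records import BeatSet, EcgRecord, FundamentalComponent, FWaveSignal

__all__ = [
    "PsdEstimate",
    "compute_fwa",
    "compute_nfwa",
    "estimate_dominant_frequency",
    "extract_fundamental",
]

DF_BAND = (3.0, 12.0)  # Hz, physiological atrial rate band
SCREEN_BAND = (3.0, 25.0)  # Hz, band used for the window-screening correlation


@dataclass
class PsdEstimate:
    """Averaged Welch PSD with window-screening bookkeeping."""

    freqs: np.ndarray
    power: np.ndarray
    window_len: int
    overlap_fraction: float
    n_windows_kept: int
    n_windows_total: int


def compute_fwa(f: FWaveSignal, mode: str = "rms") -> float:
    """Fibrillatory wave amplitude in mV.

    ``mode="rms"`` (default) returns the root-mean-square of f(n);
    ``mode="mean_square"`` returns the mean of squares instead.
    """
    x = f.samples
    if x.size == 0:
        raise ValueError("empty f-wave signal")
    ms = float(np.mean(x * x))
    if mode == "rms":
        return float(np.sqrt(ms))
    if mode == "mean_square":
        return ms
    raise ValueError(f"unknown mode {mode!r}")


def compute_nfwa(f: FWaveSignal, x: EcgRecord, beats: BeatSet, mode: str = "rms") -> float:
    """Normalized f-wave amplitude: RMS(f) over RMS of x at the R-peaks."""
    if beats.nb == 0:
        raise ValueError("nFWA requires at least one detected beat")
    if f.n_samples != x.n_samples:
        raise ValueError("f-waves and ECG must be aligned (equal length)")
    peaks = x.samples[beats.r_peaks]
    denom_ms = float(np.mean(peaks * peaks))
    if denom_ms <= 0:
        raise ValueError("zero R-peak amplitude")
    num_ms = float(np.mean(f.samples * f.samples))
    if mode == "rms":
        return float(np.sqrt(num_ms) / np.sqrt(denom_ms))
    if mode == "mean_square":
        return num_ms / denom_ms
    raise ValueError(f"unknown mode {mode!r}")


def _window_periodograms(
    x: np.ndarray, fs: float, window_len: int, overlap: float
) -> Tuple[np.ndarray, np.ndarray]:
    hop = window_len - int(round(overlap * window_len))
    hop = max(1, hop)
    win = sps.get_window("hamming", window_len)
    norm = fs * float(win @ win)
    starts = range(0, x.size - window_len + 1, hop)
    psds = []
    for s in starts:
        seg = x[s : s + window_len] * win
        spec = np.fft.rfft(seg, n=window_len)
        p = (np.abs(spec) ** 2) / norm
        p[1:-1] *= 2.0  # one-sided
        psds.append(p)
    freqs = np.fft.rfftfreq(window_len, 1.0 / fs)
    return freqs, np.array(psds)


def estimate_dominant_frequency(
    f: FWaveSignal,
    window_seconds: float = 6.0,
    overlap: float = 0.66,
    corr_threshold: float = 0.7,
) -> Tuple[float, PsdEstimate]:
    """Dominant atrial frequency from a screened Welch periodogram.

    Per-window periodograms (Hamming window of round(6 s * fs) samples --
    6144 samples at 1024 Hz -- 66% overlap, FFT length equal to the
    window) are screened: a window is kept when the Pearson correlation of
    its PSD, restricted to 3-25 Hz, with the mean PSD of the remaining
    windows reaches ``corr_threshold``.  The DF is the argmax of the
    averaged surviving PSD within 3-12 Hz.  Signals shorter than one
    window fall back to a single periodogram; if screening discards every
    window, the unscreened average is used with a warning.
    """
    x = f.samples
    fs = f.fs
    window_len = int(round(window_seconds * fs))
    if window_len > x.size:
        window_len = x.size  # single-window fallback
    freqs, psds = _window_periodograms(x, fs, window_len, overlap)
    n_total = psds.shape[0]

    kept = np.ones(n_total, dtype=bool)
    if n_total >= 2:
        band = (freqs >= SCREEN_BAND[0]) & (freqs <= SCREEN_BAND[1])
        sub = psds[:, band]
        for i in range(n_total):
            others = np.delete(sub, i, axis=0).mean(axis=0)
            a = sub[i] - sub[i].mean()
            b = others - others.mean()
            denom = np.sqrt((a @ a) * (b @ b))
            corr = float((a @ b) / denom) if denom > 0 else 0.0
            kept[i] = corr >= corr_threshold
        if not np.any(kept):
            warnings.warn(
                "window screening discarded every window; using the "
                "unscreened average",
                RuntimeWarning,
                stacklevel=2,
            )
            kept[:] = True

    avg = psds[kept].mean(axis=0)
    df_band = (freqs >= DF_BAND[0]) & (freqs <= DF_BAND[1])
    if not np.any(df_band):
        raise ValueError("spectral grid does not cover the 3-12 Hz band")
    band_freqs = freqs[df_band]
    df = float(band_freqs[int(np.argmax(avg[df_band]))])
    psd = PsdEstimate(
        freqs=freqs,
        power=avg,
        window_len=window_len,
        overlap_fraction=overlap,
        n_windows_kept=int(kept.sum()),
        n_windows_total=n_total,
    )
    return df, psd


def extract_fundamental(
    f: FWaveSignal,
    df: float,
    bandwidth: float = 5.0,
    order: int = 9,
    stopband_attenuation: float = 20.0,
) -> FundamentalComponent:
    """Band-pass the f-waves around the DF to obtain the fundamental ff(n).

    Zero-phase 9th-order Chebyshev type II band-pass, band edges at
    df +/- bandwidth/2, 20 dB stopband attenuation.  A lower edge at or
    below 0 Hz is clipped to 0.5 Hz with a warning.
    """
    if not DF_BAND[0] <= df <= DF_BAND[1]:
        raise ValueError(f"df={df} Hz outside the {DF_BAND} Hz band")
    lo = df - bandwidth / 2.0
    hi = df + bandwidth / 2.0
    if lo <= 0:
        warnings.warn(
            f"lower band edge {lo:.2f} Hz clipped to 0.5 Hz",
            RuntimeWarning,
            stacklevel=2,
        )
        lo = 0.5
    spec = FilterSpec(
        "chebyshev2-bandpass",
        order=order,
        cutoffs=(lo, hi),
        stopband_attenuation=stopband_attenuation,
    )
    y = zero_phase_filter(f.samples, spec, f.fs)
    return FundamentalComponent(samples=y, fs=f.fs, center_freq=df)
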