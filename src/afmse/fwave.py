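"""Ventricular activity removal: beat detection, template cancellation.

f-waves are isolated from the preprocessed ECG by average-beat QRST
cancellation: R-peaks are detected, beats are labeled normal/ectopic by
template matching, one average template per beat kind is built over a
window of min(470 ms, 90% of the median RR interval) centered on each
R-peak, the matching template (least-squares amplitude-scaled per beat) is
subtracted, and the residual is high-pass filtered at 3 Hz.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .preprocess import FilterSpec, zero_phase_filter
from .records import BeatSet, EcgRecord, FWaveSignal

__all__ = [
    "qrst_window_length",
    "detect_r_peaks",
    "classify_ectopics",
    "cancel_qrst",
    "segment_signal",
]

QRST_COMMON_DURATION = 0.470  # s, typical QRST complex length
REFRACTORY = 0.200  # s, minimum distance between R-peaks


def qrst_window_length(fs: float, median_rr: float) -> int:
    """Cancellation window: min(470 ms, 90% of the median RR interval)."""
    if median_rr <= 0:
        return int(round(QRST_COMMON_DURATION * fs))
    return int(min(round(QRST_COMMON_DURATION * fs), round(0.9 * median_rr * fs)))


def _beat_window(r: int, win_len: int, n: int) -> Tuple[int, int]:
    """Window [start, stop) centered on the R-peak, truncated at edges.

    Odd window lengths place the extra sample after the peak.
    """
    before = win_len // 2
    start = r - before
    stop = start + win_len
    return max(0, start), min(n, stop)


def detect_r_peaks(record: EcgRecord) -> BeatSet:
    """Detect R-peaks on a (preferably preprocessed) ECG record.

    Energy-based detection: the signal is band-passed to the QRS band
    (10-30 Hz), squared and integrated over a 120 ms window; peaks of the
    envelope above an adaptive threshold seed the beats, each refined to
    the local absolute-amplitude maximum of the ECG.  A 200 ms refractory
    period is enforced.  A flat or empty signal yields an empty BeatSet
    with a warning.
    """
    x = record.samples
    fs = record.fs
    n = x.size
    if n < int(0.5 * fs) or np.allclose(x, 0.0):
        warnings.warn("no R-peaks found", RuntimeWarning, stacklevel=2)
        return BeatSet.from_peaks(np.array([], dtype=np.int64), fs)

    # 5 Hz lower edge keeps widened (ectopic) QRS complexes detectable
    # while the squared envelope still dwarfs the much smaller f-waves
    hi = min(30.0, 0.45 * fs)
    sos = sps.butter(3, [5.0, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = band * band
    w = max(3, int(round(0.120 * fs)))
    envelope = np.convolve(energy, np.ones(w) / w, mode="same")

    scale = np.percentile(envelope, 99)
    if scale <= 0:
        warnings.warn("no R-peaks found", RuntimeWarning, stacklevel=2)
        return BeatSet.from_peaks(np.array([], dtype=np.int64), fs)
    peaks, _ = sps.find_peaks(
        envelope, height=0.2 * scale, distance=int(round(REFRACTORY * fs))
    )
    if peaks.size == 0:
        warnings.warn("no R-peaks found", RuntimeWarning, stacklevel=2)
        return BeatSet.from_peaks(np.array([], dtype=np.int64), fs)

    # refine each candidate to the local |amplitude| maximum of the ECG
    half = int(round(0.060 * fs))
    refined = []
    for p in peaks:
        lo, hi_i = max(0, p - half), min(n, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi_i]))))
    refined = np.array(sorted(set(refined)), dtype=np.int64)

    # enforce refractory period after refinement, keeping the larger peak
    keep: List[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < REFRACTORY * fs:
            if abs(x[idx]) > abs(x[keep[-1]]):
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return BeatSet.from_peaks(np.array(keep, dtype=np.int64), fs)


def _windowed_beats(
    x: np.ndarray, beats: BeatSet, win_len: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack beats with a full window; returns (matrix, full-window mask)."""
    n = x.size
    full = []
    mask = np.zeros(beats.nb, dtype=bool)
    for b, r in enumerate(beats.r_peaks):
        start, stop = _beat_window(int(r), win_len, n)
        if stop - start == win_len:
            full.append(x[start:stop])
            mask[b] = True
    matrix = np.array(full) if full else np.empty((0, win_len))
    return matrix, mask


def _zero_lag_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom <= 0:
        return 0.0
    return float((a @ b) / denom)


def classify_ectopics(
    record: EcgRecord, beats: BeatSet, threshold: float = 0.9
) -> BeatSet:
    """Label each beat normal or ectopic by template matching.

    A pointwise-median beat template is built over the QRST window; beats
    whose zero-lag normalized correlation with the template falls below
    ``threshold`` are labeled ectopic.  Fewer than 3 beats: all labeled
    normal with a warning.
    """
    if beats.nb < 3:
        warnings.warn(
            "fewer than 3 beats; all labeled normal", RuntimeWarning, stacklevel=2
        )
        return BeatSet.from_peaks(beats.r_peaks, beats.fs)

    win_len = qrst_window_length(record.fs, beats.median_rr)
    x = record.samples
    matrix, full_mask = _windowed_beats(x, beats, win_len)
    if matrix.shape[0] < 3:
        warnings.warn(
            "too few full-window beats; all labeled normal",
            RuntimeWarning,
            stacklevel=2,
        )
        return BeatSet.from_peaks(beats.r_peaks, beats.fs)

    template = np.median(matrix, axis=0)
    labels = np.full(beats.nb, "normal", dtype="U7")
    for b, r in enumerate(beats.r_peaks):
        start, stop = _beat_window(int(r), win_len, x.size)
        seg = x[start:stop]
        # align the template with a truncated edge window
        t_start = start - (int(r) - win_len // 2)
        tpl = template[t_start : t_start + seg.size]
        if _zero_lag_correlation(seg, tpl) < threshold:
            labels[b] = "ectopic"
    return BeatSet(r_peaks=beats.r_peaks, labels=labels, fs=beats.fs)


def _kind_template(
    matrix: np.ndarray, full_mask: np.ndarray, is_ectopic: np.ndarray, kind: str
) -> Optional[np.ndarray]:
    sel = (is_ectopic if kind == "ectopic" else ~is_ectopic)[full_mask]
    if not np.any(sel):
        return None
    return matrix[sel].mean(axis=0)


def cancel_qrst(
    record: EcgRecord,
    beats: BeatSet,
    highpass_hz: Optional[float] = 3.0,
    scale_per_beat: bool = True,
) -> FWaveSignal:
    """Subtract average QRST templates at every beat and isolate f-waves.

    One template per beat kind (normal/ectopic) is averaged over the beats
    of that kind; at each beat the matching template is amplitude-scaled
    by least squares (optional) and subtracted over its window.  Windows
    extending past the signal edges are truncated.  The residual is
    high-pass filtered at ``highpass_hz`` (pass None to skip, e.g. for
    inspecting the raw cancellation residual).
    """
    x = record.samples.copy()
    n = x.size
    if beats.nb == 0:
        out = x
    else:
        win_len = qrst_window_length(record.fs, beats.median_rr)
        matrix, full_mask = _windowed_beats(record.samples, beats, win_len)
        is_ect = beats.is_ectopic
        templates = {
            "normal": _kind_template(matrix, full_mask, is_ect, "normal"),
            "ectopic": _kind_template(matrix, full_mask, is_ect, "ectopic"),
        }
        if templates["normal"] is None:
            templates["normal"] = templates["ectopic"]
        if templates["ectopic"] is None:
            templates["ectopic"] = templates["normal"]
        for b, r in enumerate(beats.r_peaks):
            tpl_full = templates["ectopic" if is_ect[b] else "normal"]
            if tpl_full is None:
                continue
            start, stop = _beat_window(int(r), win_len, n)
            t_start = start - (int(r) - win_len // 2)
            tpl = tpl_full[t_start : t_start + (stop - start)]
            seg = x[start:stop]
            if scale_per_beat:
                denom = float(tpl @ tpl)
                gain = float(seg @ tpl) / denom if denom > 0 else 1.0
            else:
                gain = 1.0
            x[start:stop] = seg - gain * tpl
        out = x
    if highpass_hz is not None:
        spec = FilterSpec("butterworth-highpass", order=4, cutoffs=highpass_hz)
        out = zero_phase_filter(out, spec, record.fs)
    return FWaveSignal(samples=out, fs=record.fs)


def segment_signal(f: FWaveSignal, n_segments: int) -> List[FWaveSignal]:
    """Split into equal-length contiguous non-overlapping segments.

    Floor division; remainder samples are dropped from the tail.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    seg_len = f.n_samples // n_segments
    if seg_len == 0:
        raise ValueError("signal shorter than the number of segments")
    return [
        FWaveSignal(samples=f.samples[i * seg_len : (i + 1) * seg_len], fs=f.fs)
        for i in range(n_segments)
    ]
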