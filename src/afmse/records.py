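"""Core in-memory containers for single-lead ECG analysis.

All signals are stored as 1-D float arrays in millivolts, together with the
sampling rate in Hz.  The containers are deliberately thin: they validate
their invariants on construction and otherwise behave like annotated numpy
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcgRecord",
    "BeatSet",
    "FWaveSignal",
    "FundamentalComponent",
    "GroundTruth",
]


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("signal contains non-finite samples")
    return arr


@dataclass
class EcgRecord:
    """A single-lead ECG segment (lead-V1-like by default).

    Parameters
    ----------
    samples : array_like
        ECG samples in mV.
    fs : float
        Sampling rate in Hz.
    lead_name : str
        Lead label, informational only.
    provenance : {"raw", "preprocessed"}
        Whether the record has passed through the denoising chain.
    """

    samples: np.ndarray
    fs: float
    lead_name: str = "V1"
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.provenance not in ("raw", "preprocessed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class BeatSet:
    """Detected R-peaks with normal/ectopic labels.

    ``r_peaks`` are sample indices into the source record, strictly
    increasing.  ``labels`` holds one of ``"normal"``/``"ectopic"`` per beat.
    ``median_rr`` is the median RR interval in seconds (0 when fewer than
    two beats are available).
    """

    r_peaks: np.ndarray
    labels: np.ndarray
    fs: float
    median_rr: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype="U7")
        if self.r_peaks.size != self.labels.size:
            raise ValueError("r_peaks and labels must have equal length")
        if self.r_peaks.size > 1 and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.median_rr == 0.0 and self.r_peaks.size >= 2:
            self.median_rr = float(np.median(np.diff(self.r_peaks)) / self.fs)

    @classmethod
    def from_peaks(cls, r_peaks, fs: float, labels=None) -> "BeatSet":
        r_peaks = np.asarray(r_peaks, dtype=np.int64)
        if labels is None:
            labels = np.full(r_peaks.size, "normal", dtype="U7")
        return cls(r_peaks=r_peaks, labels=np.asarray(labels, dtype="U7"), fs=fs)

    @property
    def nb(self) -> int:
        """Number of beats."""
        return self.r_peaks.size

    @property
    def is_ectopic(self) -> np.ndarray:
        return self.labels == "ectopic"


@dataclass
class FWaveSignal:
    """Extracted atrial fibrillatory waves f(n), in mV."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class FundamentalComponent:
    """Narrowband fundamental of the f-waves, band-limited around the DF."""

    samples: np.ndarray
    fs: float
    center_freq: float

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class GroundTruth:
    """Additive decomposition and beat annotations of a synthetic record.

    The atrial, ventricular and noise components sum exactly to the
    composite ECG.  ``beat_indices`` are the true R-peak sample positions,
    ``ectopic_flags`` mark the beats synthesized with ectopic morphology.
    """

    atrial: np.ndarray
    ventricular: np.ndarray
    noise: np.ndarray
    beat_indices: np.ndarray
    ectopic_flags: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.atrial = _as_float_array(self.atrial)
        self.ventricular = _as_float_array(self.ventricular)
        self.noise = _as_float_array(self.noise)
        self.beat_indices = np.asarray(self.beat_indices, dtype=np.int64)
        self.ectopic_flags = np.asarray(self.ectopic_flags, dtype=bool)
        if not (self.atrial.size == self.ventricular.size == self.noise.size):
            raise ValueError("component signals must have equal length")
        if self.beat_indices.size != self.ectopic_flags.size:
            raise ValueError("beat_indices and ectopic_flags must match")
        if self.beat_indices.size > 1 and np.any(np.diff(self.beat_indices) <= 0):
            raise ValueError("beat_indices must be strictly increasing")

    @property
    def composite(self) -> np.ndarray:
        return self.atrial + self.ventricular + self.noise
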