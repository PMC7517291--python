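"""Synthetic persistent-AF single-lead ECG cohorts with ground truth.

The atrial component follows the standard surface-AF signal model: a sum
of harmonics of a sawtooth-like oscillation with sinusoidal amplitude and
frequency modulation, plus a per-sample random-walk phase jitter that
controls disorganization independently of the dominant frequency.  The
ventricular component is a fixed Gaussian-lobe QRST morphology placed at
i.i.d. log-normal RR intervals (AF rhythm carries no sinus correlation
structure); ectopic beats get widened, attenuated complexes with inverted
T-waves.  Noise is baseline wander, 50 Hz powerline interference and
broadband white noise - exactly the targets of the preprocessing chain.

Two cohort archetypes are provided: patients who maintain sinus rhythm
after cardioversion (lower dominant frequency, more organized f-waves) and
patients who relapse to AF (higher dominant frequency, more disorganized
f-waves, smaller normalized amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .records import EcgRecord, GroundTruth

__all__ = [
    "AtrialModelParams",
    "VentricularModelParams",
    "NoiseModelParams",
    "ArchetypeSpec",
    "CohortConfig",
    "synthesize_fwave",
    "synthesize_ecg",
    "generate_cohort",
    "default_sr_archetype",
    "default_relapse_archetype",
]

_MAX_SEED = 2**31 - 1


def _default_amplitudes(n_harmonics: int, base: float = 0.06) -> Tuple[float, ...]:
    """Sawtooth-like 1/h harmonic decay scaled to a base amplitude in mV."""
    return tuple(base / (2.0**h) for h in range(n_harmonics))


@dataclass
class AtrialModelParams:
    """Parameters of the sawtooth-harmonic atrial (f-wave) model.

    ``phase_jitter_sd`` is the per-sample standard deviation (radians) of a
    random walk added to the instantaneous phase; it is the disorganization
    knob: larger values broaden the spectrum and raise entropy.
    """

    fundamental_freq: float = 5.6
    n_harmonics: int = 3
    harmonic_amplitudes: Optional[Tuple[float, ...]] = None
    am_depth: float = 0.10
    am_freq: float = 0.5
    fm_deviation: float = 0.2
    fm_freq: float = 0.1
    phase_jitter_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3.0 <= self.fundamental_freq <= 12.0:
            raise ValueError("fundamental_freq must lie in [3, 12] Hz")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.harmonic_amplitudes is None:
            self.harmonic_amplitudes = _default_amplitudes(self.n_harmonics)
        self.harmonic_amplitudes = tuple(float(a) for a in self.harmonic_amplitudes)
        if len(self.harmonic_amplitudes) != self.n_harmonics:
            raise ValueError("need one amplitude per harmonic")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be non-negative")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")
        if self.fm_deviation < 0 or self.phase_jitter_sd < 0:
            raise ValueError("modulation parameters must be non-negative")


@dataclass
class VentricularModelParams:
    """Gaussian-lobe QRST morphology at irregular log-normal RR intervals."""

    mean_rr: float = 0.7
    rr_cv: float = 0.18
    qrs_amplitude: float = 1.0
    t_amplitude: float = 0.2
    ectopic_rate: float = 0.0
    ectopic_shape_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        if not 0.0 <= self.ectopic_rate < 1.0:
            raise ValueError("ectopic_rate must lie in [0, 1)")


@dataclass
class NoiseModelParams:
    """Baseline wander, powerline interference and broadband noise."""

    baseline_amp: float = 0.10
    baseline_freq: float = 0.33
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0
    white_noise_sd: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_noise_sd) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if not 0.0 < self.baseline_freq < 0.8:
            raise ValueError("baseline_freq must lie in (0, 0.8) Hz")


def synthesize_fwave(params: AtrialModelParams, n_samples: int, fs: float) -> np.ndarray:
    """Generate a zero-mean atrial f-wave series in mV.

    The instantaneous phase is 2*pi*f0*t plus sinusoidal FM and a Gaussian
    random-walk jitter; harmonics are phase-locked to the fundamental so
    the waveform is sawtooth-like.  With all modulation and jitter at zero
    and a single harmonic, the output degenerates to a pure sinusoid at the
    fundamental frequency.
    """
    if n_samples < fs:
        raise ValueError("need at least one second of signal")
    rng = np.random.default_rng(params.seed)
    t = np.arange(n_samples) / fs
    phase = 2.0 * np.pi * params.fundamental_freq * t
    if params.fm_deviation > 0 and params.fm_freq > 0:
        fm_phase = rng.uniform(0.0, 2.0 * np.pi)
        phase = phase + (params.fm_deviation / params.fm_freq) * np.sin(
            2.0 * np.pi * params.fm_freq * t + fm_phase
        )
    if params.phase_jitter_sd > 0:
        phase = phase + np.cumsum(rng.normal(0.0, params.phase_jitter_sd, n_samples))
    am = np.ones(n_samples)
    if params.am_depth > 0 and params.am_freq > 0:
        am_phase = rng.uniform(0.0, 2.0 * np.pi)
        am = 1.0 + params.am_depth * np.sin(2.0 * np.pi * params.am_freq * t + am_phase)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    x = np.zeros(n_samples)
    for h, amp in enumerate(params.harmonic_amplitudes, start=1):
        x += amp * np.sin(h * (phase + phi0))
    x *= am
    return x - x.mean()


def _qrst_waveform(
    fs: float, qrs_amplitude: float, t_amplitude: float, ectopic: bool, shape_scale: float
) -> Tuple[np.ndarray, int]:
    """Fixed QRST morphology from Gaussian lobes.

    Returns the waveform and the offset of the R-peak within it.  The
    morphology spans roughly -90 ms to +420 ms around the R-peak.  Ectopic
    beats are widened, attenuated and carry an inverted T-wave, scaled by
    ``shape_scale``.
    """
    width_mult = 1.0 + 0.8 * shape_scale if ectopic else 1.0
    amp_mult = 1.0 - 0.25 * shape_scale if ectopic else 1.0
    t_amp = -0.6 * shape_scale * t_amplitude if ectopic else t_amplitude
    # (center s, width s, amplitude mV); compact T-wave ~150 ms after R so
    # the whole complex fits a 470 ms window centered on the R-peak,
    # consistent with the shortened QT at AF heart rates
    lobes = [
        (-0.028, 0.010 * width_mult, -0.12 * qrs_amplitude * amp_mult),
        (0.000, 0.011 * width_mult, qrs_amplitude * amp_mult),
        (0.030, 0.012 * width_mult, -0.20 * qrs_amplitude * amp_mult),
        (0.140, 0.030, t_amp),
    ]
    t0, t1 = -0.09, 0.28
    tt = np.arange(round(t0 * fs), round(t1 * fs) + 1) / fs
    w = np.zeros(tt.size)
    for c, s, a in lobes:
        w += a * np.exp(-0.5 * ((tt - c) / s) ** 2)
    r_offset = int(-round(t0 * fs))
    return w, r_offset


def _ventricular_train(
    params: VentricularModelParams, n_samples: int, fs: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(params.seed)
    sigma2 = np.log(1.0 + params.rr_cv**2)
    mu = np.log(params.mean_rr) - sigma2 / 2.0
    duration = n_samples / fs
    beat_times = []
    t = float(rng.uniform(0.2, 0.5)) * params.mean_rr
    while t < duration:
        beat_times.append(t)
        t += float(rng.lognormal(mu, np.sqrt(sigma2)))
    beat_idx = np.array([int(round(bt * fs)) for bt in beat_times], dtype=np.int64)
    beat_idx = beat_idx[beat_idx < n_samples]
    ectopic = rng.random(beat_idx.size) < params.ectopic_rate

    normal_w, r_off = _qrst_waveform(
        fs, params.qrs_amplitude, params.t_amplitude, False, params.ectopic_shape_scale
    )
    ect_w, ect_off = _qrst_waveform(
        fs, params.qrs_amplitude, params.t_amplitude, True, params.ectopic_shape_scale
    )
    x = np.zeros(n_samples)
    for idx, is_ect in zip(beat_idx, ectopic):
        w, off = (ect_w, ect_off) if is_ect else (normal_w, r_off)
        start = idx - off
        w_lo = max(0, -start)
        w_hi = min(w.size, n_samples - start)
        if w_hi > w_lo:
            x[start + w_lo : start + w_hi] += w[w_lo:w_hi]
    return x, beat_idx, ectopic


def _noise(params: NoiseModelParams, n_samples: int, fs: float) -> np.ndarray:
    rng = np.random.default_rng(params.seed)
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    if params.baseline_amp > 0:
        out += params.baseline_amp * np.sin(
            2.0 * np.pi * params.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if params.powerline_amp > 0:
        out += params.powerline_amp * np.sin(
            2.0 * np.pi * params.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if params.white_noise_sd > 0:
        out += rng.normal(0.0, params.white_noise_sd, n_samples)
    return out


def synthesize_ecg(
    atrial: AtrialModelParams,
    ventricular: VentricularModelParams,
    noise: NoiseModelParams,
    duration: float = 90.0,
    fs: float = 1024.0,
    group_label: str = "",
) -> Tuple[EcgRecord, GroundTruth]:
    """Compose a synthetic single-lead AF ECG with additive ground truth.

    The record equals atrial + ventricular + noise exactly, and the
    decomposition is returned alongside the true beat annotations.  Output
    is bit-identical for fixed parameter seeds.
    """
    n_float = duration * fs
    n_samples = int(round(n_float))
    if abs(n_float - n_samples) > 1e-9:
        raise ValueError("duration * fs must be an integer sample count")
    a = synthesize_fwave(atrial, n_samples, fs)
    v, beat_idx, ectopic = _ventricular_train(ventricular, n_samples, fs)
    w = _noise(noise, n_samples, fs)
    record = EcgRecord(samples=a + v + w, fs=fs, provenance="raw")
    gt = GroundTruth(
        atrial=a,
        ventricular=v,
        noise=w,
        beat_indices=beat_idx,
        ectopic_flags=ectopic,
        group_label=group_label,
    )
    return record, gt


@dataclass
class ArchetypeSpec:
    """Distributional description of one patient group.

    The dominant frequency of each synthetic patient is drawn from a
    normal distribution (clipped to the physiological 3-12 Hz band); the
    remaining model parameters are shared within the group.
    """

    df_mean: float
    df_sd: float
    phase_jitter_sd: float
    atrial_base_amp: float
    n_harmonics: int = 3
    am_depth: float = 0.10
    am_freq: float = 0.5
    fm_deviation: float = 0.2
    fm_freq: float = 0.1
    ventricular: VentricularModelParams = field(default_factory=VentricularModelParams)
    noise: NoiseModelParams = field(default_factory=NoiseModelParams)

    def draw(self, rng: np.random.Generator) -> Tuple[
        AtrialModelParams, VentricularModelParams, NoiseModelParams
    ]:
        df = float(np.clip(rng.normal(self.df_mean, self.df_sd), 3.2, 11.8))
        seeds = rng.integers(0, _MAX_SEED, size=3)
        atrial = AtrialModelParams(
            fundamental_freq=df,
            n_harmonics=self.n_harmonics,
            harmonic_amplitudes=_default_amplitudes(self.n_harmonics, self.atrial_base_amp),
            am_depth=self.am_depth,
            am_freq=self.am_freq,
            fm_deviation=self.fm_deviation,
            fm_freq=self.fm_freq,
            phase_jitter_sd=self.phase_jitter_sd,
            seed=int(seeds[0]),
        )
        vent = replace(self.ventricular, seed=int(seeds[1]))
        noise = replace(self.noise, seed=int(seeds[2]))
        return atrial, vent, noise


def default_sr_archetype() -> ArchetypeSpec:
    """Group maintaining sinus rhythm: lower DF, organized, larger f-waves."""
    return ArchetypeSpec(
        df_mean=4.9, df_sd=0.4, phase_jitter_sd=0.02, atrial_base_amp=0.09
    )


def default_relapse_archetype() -> ArchetypeSpec:
    """Group relapsing to AF: higher DF, disorganized, smaller f-waves."""
    return ArchetypeSpec(
        df_mean=5.6, df_sd=0.4, phase_jitter_sd=0.06, atrial_base_amp=0.06
    )


@dataclass
class CohortConfig:
    """Two-group synthetic cohort configuration.

    Defaults mirror a 70-patient cardioversion study population: 31
    patients maintaining sinus rhythm and 39 relapsing to AF, 90 s
    single-lead records sampled at 1024 Hz.
    """

    n_sr: int = 31
    n_relapse: int = 39
    duration: float = 90.0
    fs: float = 1024.0
    master_seed: int = 0
    archetype_sr: ArchetypeSpec = field(default_factory=default_sr_archetype)
    archetype_relapse: ArchetypeSpec = field(default_factory=default_relapse_archetype)

    def __post_init__(self) -> None:
        if self.n_sr < 1 or self.n_relapse < 1:
            raise ValueError("need at least one record per group")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")


def generate_cohort(config: CohortConfig) -> List[Tuple[EcgRecord, GroundTruth]]:
    """Generate the full labeled cohort, reproducibly.

    Per-record seeds derive from the master seed through counter-based
    spawn keys (group index, record index), so each record is independent
    of cohort size and generation order.
    """
    out: List[Tuple[EcgRecord, GroundTruth]] = []
    groups = [
        ("SR", config.archetype_sr, config.n_sr),
        ("AF-relapse", config.archetype_relapse, config.n_relapse),
    ]
    for g_idx, (label, archetype, n) in enumerate(groups):
        for i in range(n):
            ss = np.random.SeedSequence(config.master_seed, spawn_key=(g_idx, i))
            rng = np.random.default_rng(ss)
            atrial, vent, noise = archetype.draw(rng)
            record, gt = synthesize_ecg(
                atrial, vent, noise, config.duration, config.fs, group_label=label
            )
            out.append((record, gt))
    return out
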