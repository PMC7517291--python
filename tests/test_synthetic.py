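"""Synthetic AF ECG generator: spectra, additivity, determinism."""

import numpy as np
import pytest

from afmse.entropy import EntropyParams, sample_entropy
from afmse.synthetic import (
    AtrialModelParams,
    CohortConfig,
    NoiseModelParams,
    VentricularModelParams,
    generate_cohort,
    synthesize_ecg,
    synthesize_fwave,
)

FS = 512.0


def fft_peak_freq(x, fs):
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    band = (freqs >= 1.0) & (freqs <= 30.0)
    return freqs[band][np.argmax(spec[band])]


def test_degenerate_single_harmonic_is_pure_sinusoid():
    p = AtrialModelParams(
        fundamental_freq=6.0,
        n_harmonics=1,
        harmonic_amplitudes=(0.1,),
        am_depth=0.0,
        fm_deviation=0.0,
        phase_jitter_sd=0.0,
        seed=3,
    )
    x = synthesize_fwave(p, int(10 * FS), FS)
    assert abs(x.mean()) < 1e-12
    assert fft_peak_freq(x, FS) == pytest.approx(6.0, abs=0.15)
    # a pure sinusoid of amplitude 0.1 has RMS 0.1/sqrt(2)
    assert np.sqrt(np.mean(x**2)) == pytest.approx(0.1 / np.sqrt(2), rel=1e-3)


def test_harmonic_fwave_spectral_peak_at_fundamental():
    p = AtrialModelParams(
        fundamental_freq=7.0,
        n_harmonics=3,
        harmonic_amplitudes=(0.05, 0.025, 0.0125),
        phase_jitter_sd=0.0,
        fm_deviation=0.0,
        am_depth=0.0,
        seed=11,
    )
    x = synthesize_fwave(p, int(20 * FS), FS)
    assert fft_peak_freq(x, FS) == pytest.approx(7.0, abs=0.1)


def test_phase_jitter_raises_entropy_on_average():
    # disorganization knob: more jitter => higher SE of the waveform
    diffs = []
    for seed in range(20):
        ses = []
        for jit in (0.01, 0.1):
            p = AtrialModelParams(
                fundamental_freq=6.0, phase_jitter_sd=jit, seed=seed
            )
            x = synthesize_fwave(p, 3000, FS)
            se, _ = sample_entropy(x[:2000], EntropyParams(m=2))
            ses.append(se)
        diffs.append(ses[1] - ses[0])
    assert np.mean(diffs) > 0


def test_components_sum_exactly_to_composite():
    record, gt = synthesize_ecg(
        AtrialModelParams(seed=1),
        VentricularModelParams(seed=2),
        NoiseModelParams(seed=3),
        duration=5.0,
        fs=FS,
    )
    assert np.array_equal(record.samples, gt.composite)


def test_zero_atrial_and_noise_leaves_pure_ventricular_train():
    record, gt = synthesize_ecg(
        AtrialModelParams(harmonic_amplitudes=(0.0, 0.0, 0.0), seed=1),
        VentricularModelParams(seed=2),
        NoiseModelParams(
            baseline_amp=0.0, powerline_amp=0.0, white_noise_sd=0.0, seed=3
        ),
        duration=5.0,
        fs=FS,
    )
    assert np.array_equal(record.samples, gt.ventricular)
    assert gt.beat_indices.size > 0


def test_beat_count_in_expected_range():
    record, gt = synthesize_ecg(
        AtrialModelParams(seed=1),
        VentricularModelParams(mean_rr=0.7, rr_cv=0.18, seed=5),
        NoiseModelParams(seed=3),
        duration=90.0,
        fs=FS,
    )
    expected = 90.0 / 0.7
    spread = 3 * 0.18 * np.sqrt(expected)
    assert expected - spread - 1 <= gt.beat_indices.size <= expected + spread + 1


def test_synthesis_is_bit_deterministic():
    args = (
        AtrialModelParams(seed=9),
        VentricularModelParams(seed=8, ectopic_rate=0.1),
        NoiseModelParams(seed=7),
    )
    r1, g1 = synthesize_ecg(*args, duration=4.0, fs=FS)
    r2, g2 = synthesize_ecg(*args, duration=4.0, fs=FS)
    assert np.array_equal(r1.samples, r2.samples)
    assert np.array_equal(g1.beat_indices, g2.beat_indices)
    assert np.array_equal(g1.ectopic_flags, g2.ectopic_flags)


def test_cohort_counts_labels_and_determinism():
    cfg = CohortConfig(n_sr=2, n_relapse=3, duration=4.0, fs=FS, master_seed=77)
    cohort = generate_cohort(cfg)
    labels = [gt.group_label for _, gt in cohort]
    assert labels.count("SR") == 2 and labels.count("AF-relapse") == 3
    cohort2 = generate_cohort(cfg)
    for (r1, _), (r2, _) in zip(cohort, cohort2):
        assert np.array_equal(r1.samples, r2.samples)


def test_minimal_cohort_has_one_record_per_group():
    cfg = CohortConfig(n_sr=1, n_relapse=1, duration=4.0, fs=FS, master_seed=1)
    cohort = generate_cohort(cfg)
    assert sorted(gt.group_label for _, gt in cohort) == ["AF-relapse", "SR"]


def test_default_cohort_mirrors_the_70_patient_split():
    cfg = CohortConfig()
    assert cfg.n_sr == 31 and cfg.n_relapse == 39
    assert cfg.duration == 90.0 and cfg.fs == 1024.0
    assert int(cfg.duration * cfg.fs) == 92160


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(fundamental_freq=2.0),
        dict(fundamental_freq=13.0),
        dict(am_depth=1.5),
        dict(harmonic_amplitudes=(-0.1, 0.1, 0.1)),
    ],
)
def test_invalid_atrial_params_rejected(kwargs):
    with pytest.raises(ValueError):
        AtrialModelParams(**kwargs)


def test_invalid_ventricular_and_noise_params_rejected():
    with pytest.raises(ValueError):
        VentricularModelParams(mean_rr=0.0)
    with pytest.raises(ValueError):
        VentricularModelParams(ectopic_rate=1.0)
    with pytest.raises(ValueError):
        NoiseModelParams(baseline_freq=0.9)
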