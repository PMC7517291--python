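"""Beat detection, ectopic labeling, QRST cancellation, segmentation."""

import numpy as np
import pytest

from conftest import make_record
from afmse.fwave import (
    cancel_qrst,
    classify_ectopics,
    detect_r_peaks,
    qrst_window_length,
    segment_signal,
)
from afmse.preprocess import FilterSpec, preprocess_ecg, zero_phase_filter
from afmse.records import EcgRecord, FWaveSignal

FS = 512.0


def detect_on(record):
    return detect_r_peaks(preprocess_ecg(record))


def match_stats(detected, truth, fs):
    """(sensitivity, max localization error in ms) of detected vs truth."""
    if truth.size == 0:
        return 1.0, 0.0
    tol = int(0.05 * fs)
    hits = 0
    errs = []
    for t in truth:
        d = np.abs(detected - t)
        if d.size and d.min() <= tol:
            hits += 1
            errs.append(d.min() / fs * 1000)
    return hits / truth.size, (max(errs) if errs else np.inf)


def test_noiseless_detection_finds_every_beat_precisely():
    record, gt = make_record(seed=1, white_noise_sd=0.0)
    beats = detect_on(record)
    sens, max_err = match_stats(beats.r_peaks, gt.beat_indices, record.fs)
    assert sens == 1.0
    assert beats.nb == gt.beat_indices.size  # no extra detections
    assert max_err <= 10.0  # ms


def test_noisy_detection_sensitivity_over_seeds():
    sens_all = []
    for seed in range(20):
        record, gt = make_record(seed=seed, white_noise_sd=0.05)
        beats = detect_on(record)
        sens, _ = match_stats(beats.r_peaks, gt.beat_indices, record.fs)
        sens_all.append(sens)
    assert np.mean(sens_all) >= 0.99


def test_flat_signal_yields_empty_beatset():
    with pytest.warns(RuntimeWarning):
        beats = detect_r_peaks(EcgRecord(np.zeros(int(5 * FS)), FS))
    assert beats.nb == 0


def test_refractory_period_enforced():
    record, _ = make_record(seed=3)
    beats = detect_on(record)
    assert np.all(np.diff(beats.r_peaks) >= 0.2 * record.fs)


def test_no_ectopics_when_rate_zero():
    record, _ = make_record(seed=5, ectopic_rate=0.0)
    pre = preprocess_ecg(record)
    beats = classify_ectopics(pre, detect_r_peaks(pre))
    assert not beats.is_ectopic.any()


def test_identical_beats_all_labeled_normal():
    record, _ = make_record(seed=2, white_noise_sd=0.0, atrial_base=0.0)
    pre = preprocess_ecg(record)
    beats = classify_ectopics(pre, detect_r_peaks(pre))
    assert not beats.is_ectopic.any()


def test_strong_ectopics_recovered_over_seeds():
    found, total = 0, 0
    for seed in range(20):
        record, gt = make_record(seed=seed, ectopic_rate=0.12, duration=20.0)
        if not gt.ectopic_flags.any():
            continue
        pre = preprocess_ecg(record)
        beats = classify_ectopics(pre, detect_r_peaks(pre))
        ect_idx = beats.r_peaks[beats.is_ectopic]
        for t in gt.beat_indices[gt.ectopic_flags]:
            total += 1
            if ect_idx.size and np.abs(ect_idx - t).min() <= 0.05 * record.fs:
                found += 1
    assert total > 0
    assert found / total >= 0.8


def test_too_few_beats_labeled_normal_with_warning():
    record, _ = make_record(seed=4, duration=10.0)
    pre = preprocess_ecg(record)
    beats = detect_r_peaks(pre)
    from afmse.records import BeatSet

    two = BeatSet.from_peaks(beats.r_peaks[:2], pre.fs)
    with pytest.warns(RuntimeWarning):
        out = classify_ectopics(pre, two)
    assert list(out.labels) == ["normal", "normal"]


def test_cancellation_of_pure_ventricular_train_leaves_tiny_residual():
    # identical beats, no atrial activity, no noise: the average template
    # equals every beat and the subtraction must be near-exact
    from afmse.synthetic import (
        AtrialModelParams,
        NoiseModelParams,
        VentricularModelParams,
        synthesize_ecg,
    )

    record, gt = synthesize_ecg(
        AtrialModelParams(harmonic_amplitudes=(0.0, 0.0, 0.0), seed=6),
        VentricularModelParams(seed=106),
        NoiseModelParams(baseline_amp=0.0, powerline_amp=0.0,
                         white_noise_sd=0.0, seed=1),
        duration=10.0,
        fs=FS,
    )
    beats = classify_ectopics(record, detect_r_peaks(record))
    resid = cancel_qrst(record, beats, highpass_hz=None)
    qrs_peak = np.max(np.abs(record.samples))
    # exclude edge-truncated beats from the residual assessment
    n = resid.n_samples
    core = resid.samples[int(1.0 * FS) : n - int(1.0 * FS)]
    assert np.sqrt(np.mean(core**2)) <= 0.02 * qrs_peak


def test_cancellation_untouched_outside_beat_windows():
    record, _ = make_record(seed=8)
    pre = preprocess_ecg(record)
    beats = classify_ectopics(pre, detect_r_peaks(pre))
    resid = cancel_qrst(pre, beats, highpass_hz=None)
    win = qrst_window_length(pre.fs, beats.median_rr)
    mask = np.ones(pre.n_samples, dtype=bool)
    for r in beats.r_peaks:
        lo = max(0, int(r) - win // 2)
        mask[lo : lo + win] = False
    assert np.array_equal(resid.samples[mask], pre.samples[mask])


def test_recovered_fwaves_correlate_with_true_atrial_component():
    band = FilterSpec("chebyshev2-bandpass", order=6, cutoffs=(3.0, 25.0),
                      stopband_attenuation=30.0)
    corrs = []
    for seed in range(10):
        record, gt = make_record(seed=seed, duration=15.0)
        pre = preprocess_ecg(record)
        beats = classify_ectopics(pre, detect_r_peaks(pre))
        fw = cancel_qrst(pre, beats)
        a = zero_phase_filter(gt.atrial, band, record.fs)
        b = zero_phase_filter(fw.samples, band, record.fs)
        corrs.append(np.corrcoef(a, b)[0, 1])
    assert np.mean(corrs) >= 0.90


def test_fwa_of_extracted_fwaves_tracks_ground_truth():
    from afmse.predictors import compute_fwa

    ratios = []
    for seed in range(8):
        record, gt = make_record(seed=seed, duration=15.0)
        pre = preprocess_ecg(record)
        beats = classify_ectopics(pre, detect_r_peaks(pre))
        fw = cancel_qrst(pre, beats)
        fwa_est = compute_fwa(fw)
        fwa_true = compute_fwa(FWaveSignal(gt.atrial, record.fs))
        ratios.append(fwa_est / fwa_true)
    assert abs(np.mean(ratios) - 1.0) <= 0.2


def test_qrst_window_length_examples():
    # common QRST duration wins over 90% of a 0.7 s RR interval
    assert qrst_window_length(1024.0, 0.7) == round(0.470 * 1024)  # 481
    # short RR: 90% of the median RR wins
    assert qrst_window_length(1024.0, 0.4) == round(0.9 * 0.4 * 1024)


def test_segmentation_lengths_and_floor_rule():
    f = FWaveSignal(np.arange(92160, dtype=float), 1024.0)
    segs = segment_signal(f, 3)
    assert [s.n_samples for s in segs] == [30720, 30720, 30720]
    assert np.array_equal(segs[1].samples, f.samples[30720:61440])

    small = FWaveSignal(np.arange(10, dtype=float), 10.0)
    segs = segment_signal(small, 3)
    assert [s.n_samples for s in segs] == [3, 3, 3]
    assert segs[-1].samples[-1] == 8.0  # last sample dropped

    same = segment_signal(small, 1)
    assert np.array_equal(same[0].samples, small.samples)

    with pytest.raises(ValueError):
        segment_signal(small, 0)
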