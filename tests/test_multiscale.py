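"""Coarse graining, entropy profiles and region features."""

import numpy as np
import pytest

from afmse.entropy import EntropyParams, sample_entropy
from afmse.multiscale import (
    ScaleProfile,
    average_segments,
    coarse_grain,
    entropy_profile,
    profile_features,
    refined_coarse_grain,
)


def test_coarse_grain_examples_and_floor_lengths():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert np.array_equal(coarse_grain(x, 1), x)
    assert np.array_equal(coarse_grain(x, 2, 0), [1.5, 3.5, 5.5])
    assert np.array_equal(coarse_grain(x, 2, 1), [2.5, 4.5])
    assert coarse_grain(np.zeros(30720), 40).size == 768
    # always floor((N - offset) / tau)
    for n, tau, off in [(100, 7, 0), (100, 7, 3), (13, 5, 4), (40, 40, 0)]:
        assert coarse_grain(np.zeros(n), tau, off).size == (n - off) // tau


def test_coarse_grain_invalid_args():
    x = np.arange(10.0)
    with pytest.raises(ValueError):
        coarse_grain(x, 0)
    with pytest.raises(ValueError):
        coarse_grain(x, 3, 3)
    with pytest.raises(ValueError):
        coarse_grain(x, 11)


def test_refined_scale1_is_identity(rng):
    x = rng.normal(size=2048)
    y, r_hat = refined_coarse_grain(x, 1)
    assert np.array_equal(y, x)
    assert r_hat == pytest.approx(0.2 * np.std(x))


def test_refined_lowpass_shrinks_white_noise_sd():
    shrunk = 0
    for seed in range(20):
        x = np.random.default_rng(seed).normal(size=4096)
        y, _ = refined_coarse_grain(x, 4)
        if np.std(y) < np.std(x):
            shrunk += 1
    assert shrunk == 20


def test_refined_attenuates_high_frequency_tone():
    fs = 1000.0
    t = np.arange(8192) / fs
    x = np.sin(2 * np.pi * 0.45 * fs * t)
    y, _ = refined_coarse_grain(x, 2)  # cutoff at 0.25 of fs
    in_amp = np.sqrt(2 * np.mean(x**2))
    out_amp = np.sqrt(2 * np.mean(y[100:-100] ** 2))
    assert 20 * np.log10(in_amp / out_amp) >= 30.0


def test_scale1_collapse_mse_cmse_equal_se(rng):
    for _ in range(5):
        x = rng.normal(size=400)
        se, _ = sample_entropy(x, EntropyParams(m=2))
        for method in ("MSE", "CMSE"):
            prof = entropy_profile(x, method, tau_max=1)
            assert prof.entropy[0] == se  # bit-for-bit
        prof_r = entropy_profile(x, "RMSE", tau_max=1)
        assert prof_r.entropy[0] == pytest.approx(se, rel=0.01)


def test_white_noise_mse_decreases_with_scale(rng):
    # fixed r makes the relative tolerance grow ~sqrt(tau): entropy drops
    x = rng.normal(size=8192)
    prof = entropy_profile(x, "MSE", tau_max=4)
    e = prof.entropy
    assert e[0] > e[1] > e[3]


def test_cmse_averages_all_offsets():
    rng = np.random.default_rng(5)
    x = rng.normal(size=600)
    params = EntropyParams(m=2)
    r0 = 0.2 * np.std(x)
    prof = entropy_profile(x, "CMSE", params, tau_max=3)
    manual = np.mean(
        [
            sample_entropy(
                coarse_grain(x, 3, k), EntropyParams(m=2, r=r0, r_mode="absolute")
            )[0]
            for k in range(3)
        ]
    )
    assert prof.entropy[2] == pytest.approx(manual, rel=1e-12)


def test_profile_feature_conventions():
    scales = np.arange(1, 41)
    flat = ScaleProfile(
        method="MSE",
        scales=scales,
        entropy=np.ones(40),
        flags=np.ones(40, bool),
        source_len=30720,
    )
    feats = profile_features(flat)
    assert feats.ahs == pytest.approx(20.0)
    assert feats.shs == pytest.approx(0.0, abs=1e-12)
    assert feats.als == pytest.approx(10.0)

    linear = ScaleProfile(
        method="RMSE",
        scales=scales,
        entropy=0.02 * scales,
        flags=np.ones(40, bool),
        source_len=30720,
    )
    feats = profile_features(linear)
    assert feats.shs == pytest.approx(0.02, rel=1e-9)
    assert feats.sls == pytest.approx(0.02, rel=1e-9)
    # area identity: AHS equals 20 x the mean entropy over tau 21..40
    assert feats.ahs == pytest.approx(20 * np.mean(0.02 * scales[20:40]))
    assert feats.best_scale == 39
    assert feats.best_scale_entropy == pytest.approx(0.02 * 39)


def test_flagged_scales_excluded_from_features():
    scales = np.arange(1, 41)
    entropy = np.ones(40)
    flags = np.ones(40, bool)
    entropy[25] = np.nan
    flags[25] = False
    prof = ScaleProfile("MSE", scales, entropy, flags, 30720)
    feats = profile_features(prof)
    assert feats.ahs == pytest.approx(19.0)  # one scale dropped

    all_bad = ScaleProfile(
        "MSE", scales, np.full(40, np.nan), np.zeros(40, bool), 30720
    )
    feats = profile_features(all_bad)
    assert np.isnan(feats.ahs) and np.isnan(feats.shs)


def test_average_segments_rules():
    assert average_segments([0.8, 1.0, 1.2]).value == pytest.approx(1.0)
    avg = average_segments([0.8, np.nan, 1.2])
    assert avg.value == pytest.approx(1.0) and avg.n_used == 2
    same = average_segments([0.5, 0.5, 0.5])
    assert same.value == 0.5 and same.n_used == 3
    flagged = average_segments([np.nan, np.nan])
    assert np.isnan(flagged.value) and flagged.n_used == 0
    with pytest.raises(ValueError):
        average_segments([])


def test_profile_long_format_export(rng):
    prof = entropy_profile(rng.normal(size=300), "MSE", tau_max=3)
    frame = prof.to_frame(record_id="rec001", segment=2)
    assert list(frame.columns) == [
        "record_id", "segment", "method", "tau", "entropy", "valid",
    ]
    assert list(frame["tau"]) == [1, 2, 3]
    assert (frame["method"] == "MSE").all()


def test_entropy_profile_rejects_unknown_method(rng):
    with pytest.raises(ValueError):
        entropy_profile(rng.normal(size=100), "FUZZY", tau_max=2)
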