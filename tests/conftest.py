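import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose the oracle helpers

from afmse.synthetic import (
    AtrialModelParams,
    NoiseModelParams,
    VentricularModelParams,
    synthesize_ecg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    seed: int = 0,
    duration: float = 10.0,
    fs: float = 512.0,
    jitter: float = 0.04,
    fundamental: float = 5.5,
    white_noise_sd: float = 0.01,
    ectopic_rate: float = 0.0,
    atrial_base: float = 0.06,
):
    """A small synthetic AF record for unit tests."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    atrial = AtrialModelParams(
        fundamental_freq=fundamental,
        phase_jitter_sd=jitter,
        harmonic_amplitudes=(atrial_base, atrial_base / 2, atrial_base / 4),
        seed=int(seeds[0]),
    )
    vent = VentricularModelParams(
        ectopic_rate=ectopic_rate, ectopic_shape_scale=1.0, seed=int(seeds[1])
    )
    noise = NoiseModelParams(white_noise_sd=white_noise_sd, seed=int(seeds[2]))
    return synthesize_ecg(atrial, vent, noise, duration=duration, fs=fs)


@pytest.fixture
def af_record():
    return make_record(seed=7)
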