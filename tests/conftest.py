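"""Shared fixtures for the pulsebp test suite."""

import numpy as np
import pytest

from pulsebp.preprocess import Beat, condition_signal, segment_beats
from pulsebp.synthgen import BeatParams, RecordSpec, simulate_beat, simulate_record


@pytest.fixture(scope="session")
def standard_params():
    return BeatParams()


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless, jitter-free 30-beat record at 1.2 Hz (the t1/t2 setup)."""
    spec = RecordSpec(
        heart_rate=1.2, n_beats=30, fs=500.0,
        noise_sd=0.0, resp_amp=0.0, beat_jitter=0.0, seed=0,
    )
    return simulate_record(spec), spec


@pytest.fixture(scope="session")
def noisy_record():
    spec = RecordSpec(heart_rate=1.2, n_beats=30, fs=500.0, seed=7)
    return simulate_record(spec), spec


@pytest.fixture(scope="session")
def clean_beats(clean_record):
    record, spec = clean_record
    conditioned = condition_signal(record.samples, spec.fs)
    return segment_beats(conditioned, spec.fs)


@pytest.fixture(scope="session")
def one_beat(standard_params):
    """A single synthetic beat wrapped as a Beat (no filtering)."""
    fs = 500.0
    samples = simulate_beat(standard_params, fs)
    return Beat(samples=samples, fs=fs, onset_index=0, period=standard_params.period)


def random_valid_params(rng: np.random.Generator) -> BeatParams:
    """Draw random BeatParams inside the documented valid region."""
    width_main = rng.uniform(0.05, 0.09)
    d1 = rng.uniform(0.18, 0.26)
    return BeatParams(
        amplitude_main=rng.uniform(0.5, 2.0),
        amp_ratio_rebound1=rng.uniform(0.2, 0.8),
        amp_ratio_rebound2=rng.uniform(0.1, 0.4),
        delay_rebound1=d1,
        delay_rebound2=d1 + rng.uniform(0.10, 0.20),
        width_main=width_main,
        width_r1=rng.uniform(0.04, 0.06),
        width_r2=rng.uniform(0.04, 0.06),
        period=rng.uniform(0.7, 1.1),
    )
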