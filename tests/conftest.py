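import numpy as np
import pytest

import phonesense as ps


@pytest.fixture(scope="session")
def day5hz():
    """One synthetic day at 5 Hz with its ground-truth schedule."""
    profile = ps.sample_profile(4, seed=42)
    profile.participant_id = "p01"
    record, schedule = ps.generate_day(profile, rate=5.0, seed=42)
    return record, schedule


@pytest.fixture(scope="session")
def small_cohort():
    """A 6x6-day cohort at 0.2 Hz: features, severities, schedules."""
    return ps.cohort_feature_matrix(6, 6, rate=0.2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_accel_stream(minute_mags, rate=5.0, day_start_ms=0):
    """Build a scalar accel-magnitude stream from per-minute |Δa| scales.

    ``minute_mags`` maps each minute of the day to the magnitude of the
    alternating deviation, so consecutive-sample changes approximate
    that magnitude.
    """
    spm = int(round(rate * 60))
    mags = np.repeat(np.asarray(minute_mags, dtype=float), spm)
    n = mags.size
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    values = 9.8 + sign * mags / 2.0
    ts = day_start_ms + np.arange(n, dtype=np.int64) * round(1000 / rate)
    return ps.SensorStream("accelerometer", ts,
                           np.column_stack([values, np.zeros(n), np.zeros(n)]),
                           rate)


def make_light_stream(minute_lux, rate=5.0, day_start_ms=0):
    spm = int(round(rate * 60))
    lux = np.repeat(np.asarray(minute_lux, dtype=float), spm)
    ts = day_start_ms + np.arange(lux.size, dtype=np.int64) * round(1000 / rate)
    return ps.SensorStream("light", ts, lux, rate)
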