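"""Scalar feature statistics and windowed event detectors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phonesense as ps
from phonesense.features import DetectorConfig

from conftest import make_accel_stream, make_light_stream

finite_series = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2,
    max_size=50)


# ---------------------------------------------------------------------------
# scalar statistics


class TestAarc:
    def test_worked_example(self):
        assert ps.aarc([1, 3, 2]) == pytest.approx(1.5)

    def test_constant_series_is_zero(self):
        assert ps.aarc([7.0] * 10) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(finite_series)
    def test_matches_loop_oracle(self, xs):
        total = sum(abs(xs[i + 1] - xs[i]) for i in range(len(xs) - 1))
        assert ps.aarc(xs) == pytest.approx(total / (len(xs) - 1), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ps.aarc([1.0])


class TestMeanAndExceedance:
    def test_mean_examples(self):
        assert ps.mean_value([2, 4]) == 3
        assert ps.mean_value([5.5] * 9) == 5.5

    def test_exceedance_abs_mode(self):
        assert ps.exceedance_frequency([0.05, 0.2, -0.3], 0.1, "abs") == \
            pytest.approx(2 / 3)

    def test_exceedance_all_below(self):
        assert ps.exceedance_frequency([1, 2, 3], 10, "raw") == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(finite_series, st.floats(min_value=0, max_value=50))
    def test_exceedance_matches_counting_oracle(self, xs, thr):
        count = sum(1 for x in xs if abs(x) > thr)
        got = ps.exceedance_frequency(xs, thr, "abs")
        assert got == pytest.approx(count / len(xs), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.mean_value([])
        with pytest.raises(ValueError):
            ps.exceedance_frequency([], 1.0)


class TestIqr:
    def test_integer_positions(self):
        # n=7: Q1 at position 2, Q3 at position 6
        assert ps.iqr([1, 2, 3, 4, 5, 6, 7]) == pytest.approx(4.0)

    def test_fractional_positions(self):
        # n=8: positions 2.25 and 6.75 -> mean of adjacent order stats
        assert ps.iqr(list(range(1, 9))) == pytest.approx(4.0)
        xs = sorted(range(1, 9))
        q1 = (xs[1] + xs[2]) / 2
        q3 = (xs[5] + xs[6]) / 2
        assert ps.iqr(xs) == pytest.approx(q3 - q1)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=-50, max_value=50, allow_nan=False),
                    min_size=4, max_size=40),
           st.randoms(use_true_random=False))
    def test_non_negative_and_permutation_invariant(self, xs, rnd):
        base = ps.iqr(xs)
        assert base >= 0
        shuffled = list(xs)
        rnd.shuffle(shuffled)
        assert ps.iqr(shuffled) == pytest.approx(base)

    def test_matches_positional_rule_oracle(self, rng):
        # independent re-application of the stated rule: value at
        # position (n+1)/4 resp. 3(n+1)/4, averaging adjacent order
        # statistics at fractional positions
        import math

        def oracle(xs):
            s = sorted(xs)
            out = []
            for pos in ((len(s) + 1) / 4, 3 * (len(s) + 1) / 4):
                if pos == int(pos):
                    out.append(s[int(pos) - 1])
                else:
                    out.append((s[math.floor(pos) - 1] +
                                s[math.ceil(pos) - 1]) / 2)
            return out[1] - out[0]

        for n in (4, 5, 7, 8, 10, 23, 40):
            xs = rng.normal(size=n)
            assert ps.iqr(xs) == pytest.approx(oracle(xs), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ps.iqr([1, 2, 3])


class TestSkewness:
    def test_symmetric_is_zero(self):
        assert ps.skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_mirror_antisymmetry(self, rng):
        xs = rng.normal(size=30) ** 2
        assert ps.skewness(10 - xs) == pytest.approx(-ps.skewness(xs))

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            xs = rng.normal(size=rng.integers(5, 50))
            n = len(xs)
            mean = sum(xs) / n
            sd = (sum((x - mean) ** 2 for x in xs) / (n - 1)) ** 0.5
            expect = n / ((n - 1) * (n - 2)) * \
                sum(((x - mean) / sd) ** 3 for x in xs)
            assert ps.skewness(xs) == pytest.approx(expect, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            ps.skewness([3.0] * 10)


class TestSpectral:
    def test_sinusoid_centroid_and_narrow_bandwidth(self):
        # bin-aligned tone: integer number of cycles, so no leakage
        rate, f0, n = 50.0, 5.0, 4000
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * f0 * t)
        freqs, power = ps.power_spectrum(x, rate)
        fc, bw = ps.spectral_moments(freqs, power)
        bin_width = rate / n
        assert fc == pytest.approx(f0, abs=2 * bin_width)
        assert bw <= 2 * bin_width

    def test_two_equal_sinusoids_centroid_at_midpoint(self):
        rate, n = 50.0, 4000
        t = np.arange(n) / rate
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        fc, _ = ps.spectral_moments(*ps.power_spectrum(x, rate))
        assert fc == pytest.approx(10.0, abs=0.1)

    def test_slope_exact_on_constructed_linear_psd(self):
        f = np.linspace(0, 10, 40)
        p = 3.5 * f + 2.0
        assert ps.slope_from_spectrum(f, p) == pytest.approx(3.5, rel=1e-12)

    def test_white_noise_slope_near_zero(self, rng):
        slopes = []
        for _ in range(50):
            x = rng.normal(size=512)
            freqs, power = ps.power_spectrum(x, 10.0)
            slopes.append(ps.slope_from_spectrum(freqs, power) /
                          np.mean(power))
        assert abs(np.mean(slopes)) < 0.05

    def test_slope_matches_polyfit_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(64, 512))
            freqs, power = ps.power_spectrum(x, 20.0)
            expect = np.polyfit(freqs, power, 1)[0]
            assert ps.slope_from_spectrum(freqs, power) == \
                pytest.approx(expect, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ps.spectral_bandwidth(np.zeros(64), 10.0)
        with pytest.raises(ValueError):
            ps.slope_from_spectrum([1.0, 1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            ps.spectral_slope(np.arange(4), 10.0)


class TestActivityAndMeals:
    def test_constant_stream_zero_minutes(self):
        s = ps.magnitude(make_accel_stream(np.zeros(1440), rate=0.2))
        assert ps.activity_duration(s) == 0.0

    def test_600_exceedances_at_10hz_is_one_minute(self):
        # 601 samples alternating by +-4 -> 600 changes above 2.5
        vals = 9.8 + 2.0 * np.where(np.arange(601) % 2 == 0, 1, -1)
        ts = np.arange(601, dtype=np.int64) * 100
        s = ps.SensorStream("accelerometer", ts,
                            np.column_stack([vals, 0 * vals, 0 * vals]), 10.0)
        assert ps.activity_duration(ps.magnitude(s)) == pytest.approx(1.0)

    def test_activity_matches_counting_oracle(self, rng):
        vals = 9.8 + rng.normal(0, 2, 500)
        ts = np.arange(500, dtype=np.int64) * 200
        s = ps.SensorStream(
            "accelerometer", ts,
            np.column_stack([vals, 0 * vals, 0 * vals]), 5.0)
        count = int(np.sum(np.abs(np.diff(vals)) > 2.5))
        assert ps.activity_duration(ps.magnitude(s)) == \
            pytest.approx(count / 5.0 / 60.0)

    def test_meal_time_deviation_examples(self):
        assert np.allclose(ps.meal_time_deviation([720, 740]), [-10, 10])
        assert np.allclose(ps.meal_time_deviation([700] * 5), 0)

    def test_meal_time_deviations_sum_to_zero(self, rng):
        t = rng.uniform(600, 900, 14)
        dev = ps.meal_time_deviation(t)
        assert np.allclose(dev, t - t.mean())
        assert dev.sum() == pytest.approx(0.0, abs=1e-9)

    def test_single_day_rejected(self):
        with pytest.raises(ValueError):
            ps.meal_time_deviation([720])


# ---------------------------------------------------------------------------
# detectors

CFG = DetectorConfig()
RATE = 5.0


def quiet_then_active(active_from_min, quiet_mag=0.2, active_mag=3.0):
    mags = np.full(1440, quiet_mag)
    mags[active_from_min:] = active_mag
    return ps.magnitude(make_accel_stream(mags, rate=RATE))


class TestBedtimeAccel:
    def test_quiet_from_0100_detected_at_0100(self):
        mags = np.full(1440, 3.0)
        mags[60:300] = 0.2  # still from 01:00 through the night window
        s = ps.magnitude(make_accel_stream(mags, rate=RATE))
        t = ps.detect_bedtime_accel(s, CFG, 0)
        assert t == pytest.approx(60.0, abs=1.0 / 60 / RATE + 1 / RATE)

    def test_restless_night_gives_absent(self):
        s = ps.magnitude(make_accel_stream(np.full(1440, 3.0), rate=RATE))
        assert ps.detect_bedtime_accel(s, CFG, 0) is None

    def test_stillness_outside_search_window_not_reported(self):
        mags = np.full(1440, 3.0)
        mags[360:] = 0.2  # quiet starts 06:00, after the window closes
        s = ps.magnitude(make_accel_stream(mags, rate=RATE))
        assert ps.detect_bedtime_accel(s, CFG, 0) is None


class TestWakeup:
    def test_activity_from_0730_detected(self):
        t = ps.detect_wakeup(quiet_then_active(450), CFG, 0)
        assert t is not None
        # earliest window with >= 50% movement can start half a window early
        assert abs(t - 450.0) <= CFG.wake_window_s / 60.0

    def test_fully_quiet_day_absent(self):
        s = ps.magnitude(make_accel_stream(np.full(1440, 0.2), rate=RATE))
        assert ps.detect_wakeup(s, CFG, 0) is None

    def test_exactly_half_exceedances_is_detected(self):
        # a half-window burst of changes exactly at the +-2 threshold:
        # the best window holds exactly 50% qualifying changes, which
        # the inclusive >= rule must accept
        n = 1440 * int(RATE * 60)
        w = int(CFG.wake_window_s * RATE)  # changes per window
        mags = np.zeros(n)
        start = int(480 * 60 * RATE)  # 08:00
        mags[start:start + w // 2 + 1] = 2.0  # w//2 interior changes == 2
        sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        vals = 9.8 + sign * mags / 2.0
        ts = np.arange(n, dtype=np.int64) * round(1000 / RATE)
        s = ps.SensorStream(
            "accelerometer", ts,
            np.column_stack([vals, 0 * vals, 0 * vals]), RATE)
        assert ps.detect_wakeup(ps.magnitude(s), CFG, 0) is not None


class TestOuting:
    def _streams(self, lux_day, accel_mag_day):
        lux = np.full(1440, 300.0)
        lux[540:570] = lux_day  # 09:00-09:30
        mags = np.full(1440, 0.5)
        mags[540:570] = accel_mag_day
        return (make_light_stream(lux, rate=RATE),
                ps.magnitude(make_accel_stream(mags, rate=RATE)))

    def test_bright_and_moving_morning_is_outing(self):
        light, accel = self._streams(1200.0, 4.0)
        assert ps.detect_outing(light, accel, "morning", CFG, 0) is True

    def test_dim_light_fails_morning_even_with_movement(self):
        light, accel = self._streams(800.0, 4.0)
        assert ps.detect_outing(light, accel, "morning", CFG, 0) is False

    def test_bright_but_still_fails_morning(self):
        light, accel = self._streams(1200.0, 0.5)
        assert ps.detect_outing(light, accel, "morning", CFG, 0) is False

    def test_evening_uses_acceleration_only(self):
        lux = np.full(1440, 200.0)  # dark throughout
        mags = np.full(1440, 0.5)
        mags[1050:1080] = 4.0  # 17:30-18:00
        light = make_light_stream(lux, rate=RATE)
        accel = ps.magnitude(make_accel_stream(mags, rate=RATE))
        assert ps.detect_outing(light, accel, "evening", CFG, 0) is True
        assert ps.detect_outing(light, accel, "afternoon", CFG, 0) is False


class TestBedtimeLight:
    def test_dark_from_2340_detected(self):
        lux = np.full(1440, 30.0)
        lux[1420:] = 0.3
        s = make_light_stream(lux, rate=RATE)
        t = ps.detect_bedtime_light(s, CFG, 0)
        assert t == pytest.approx(1420.0, abs=1.0 / RATE)

    def test_flickering_night_absent(self):
        s = make_light_stream(np.full(1440, 5.0), rate=RATE)
        assert ps.detect_bedtime_light(s, CFG, 0) is None

    def test_single_dark_sample_not_enough(self):
        lux = np.full(1440 * int(RATE * 60), 5.0)
        lux[int(1410 * RATE * 60)] = 0.3  # one isolated dark sample
        ts = np.arange(lux.size, dtype=np.int64) * round(1000 / RATE)
        s = ps.SensorStream("light", ts, lux, RATE)
        assert ps.detect_bedtime_light(s, CFG, 0) is None

    def test_wrapped_search_prefers_pre_midnight(self):
        lux = np.full(1440, 30.0)
        lux[90:300] = 0.3     # post-midnight stillness at 01:30
        lux[1380:] = 0.3      # but screen went dark at 23:00
        s = make_light_stream(lux, rate=RATE)
        assert ps.detect_bedtime_light(s, CFG, 0) == pytest.approx(
            1380.0, abs=1.0 / RATE)


# ---------------------------------------------------------------------------
# full-day assembly


class TestExtractFeatureVector:
    def test_matches_generated_schedule(self, day5hz):
        record, schedule = day5hz
        fv = ps.extract_feature_vector(record)
        assert abs(fv.values["bedtime_accel"] - schedule.bedtime_minutes) <= \
            CFG.bedtime_window_s / 60 + 1
        assert abs(fv.values["wake_time"] - schedule.wake_minutes) <= \
            CFG.wake_window_s / 60 + 1
        assert abs(fv.values["bedtime_light"] - schedule.bedtime_minutes) <= \
            CFG.light_bedtime_window_s / 60 + 1
        for slot in ("morning", "noon", "afternoon", "evening"):
            assert fv.values[f"out_{slot}"] == float(schedule.outings[slot])

    def test_schema_is_stable(self, day5hz):
        record, _ = day5hz
        fv = ps.extract_feature_vector(record)
        assert list(fv.values) == ps.FEATURE_COLUMNS
        assert len(ps.FEATURE_COLUMNS) == 20  # 18 features, IQR per axis

    def test_all_quiet_day_degenerates_gracefully(self):
        from datetime import date
        rec = ps.DayRecord("p1", date(2024, 1, 1))
        n = 1440 * int(RATE * 60)
        ts = rec.day_start_ms + np.arange(n, dtype=np.int64) * \
            round(1000 / RATE)
        const3 = np.full((n, 3), [0.0, 0.0, 9.8])
        rec.streams["accelerometer"] = ps.SensorStream(
            "accelerometer", ts, const3, RATE)
        rec.streams["gyroscope"] = ps.SensorStream(
            "gyroscope", ts, np.zeros((n, 3)), RATE)
        rec.streams["light"] = ps.SensorStream(
            "light", ts, np.full(n, 0.5), RATE)
        fv = ps.extract_feature_vector(rec)
        assert fv.values["aarc"] == 0.0
        assert fv.values["gacr"] == 0.0
        for slot in ("morning", "noon", "afternoon", "evening"):
            assert fv.values[f"out_{slot}"] == 0.0
        assert np.isnan(fv.values["skewness"])

    def test_missing_stream_rejected(self, day5hz):
        from copy import copy
        record, _ = day5hz
        broken = copy(record)
        broken.streams = {k: v for k, v in record.streams.items()
                          if k != "light"}
        with pytest.raises(ValueError):
            ps.extract_feature_vector(broken)

    def test_invariant_to_timestamp_translation(self, day5hz):
        from datetime import timedelta
        record, _ = day5hz
        shift_days = 3
        shifted = ps.DayRecord(record.participant_id,
                               record.date + timedelta(days=shift_days))
        for kind, s in record.streams.items():
            shifted.streams[kind] = ps.SensorStream(
                kind, s.timestamps + shift_days * 86400_000, s.values,
                s.nominal_rate)
        a = ps.extract_feature_vector(record).values
        b = ps.extract_feature_vector(shifted).values
        for col in ps.FEATURE_COLUMNS:
            if np.isnan(a[col]):
                assert np.isnan(b[col])
            else:
                assert a[col] == pytest.approx(b[col], rel=1e-12)

    def test_axis_sign_flip_leaves_magnitude_features_unchanged(self, day5hz):
        record, _ = day5hz
        flipped = ps.DayRecord(record.participant_id, record.date)
        for kind, s in record.streams.items():
            vals = -s.values if kind != "light" else s.values
            flipped.streams[kind] = ps.SensorStream(
                kind, s.timestamps, vals, s.nominal_rate)
        a = ps.extract_feature_vector(record).values
        b = ps.extract_feature_vector(flipped).values
        for col in ("aarc", "gacr", "gyro_gt_0p1_freq", "mean_accel",
                    "mean_gyro"):
            assert a[col] == pytest.approx(b[col], rel=1e-12)
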