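"""Per-day behavioral feature extraction from smartphone sensor streams.

Eighteen features are computed for each participant-day:

==== ======================= ====================================================
#    column                  meaning
==== ======================= ====================================================
1    aarc                    mean |Δa| between consecutive acceleration samples
2    mean_accel              mean acceleration magnitude
3    gacr                    mean |Δω| between consecutive gyroscope samples
4    gyro_gt_0p1_freq        fraction of samples with |ω| > 0.1 rad/s
5    mean_gyro               mean gyroscope magnitude
6    mean_light              mean ambient light (lux)
7    light_gt_1000_freq      fraction of light samples > 1000 lux (outdoor proxy)
8    iqr_x / iqr_y / iqr_z   per-axis accelerometer interquartile range
9    skewness                adjusted sample skewness of acceleration magnitude
10   spectral_bandwidth      power-weighted spread of the acceleration spectrum
11   spectral_slope          OLS slope of the PSD against frequency
12   bedtime_accel           first sustained-stillness time in [00:00, 05:00)
13   wake_time               first sustained-movement time in [05:00, 12:00)
14-17 out_morning..evening   slot-wise outing detections (light + movement)
18   bedtime_light           first screen-dark time (lux stays within [0, 1])
==== ======================= ====================================================

The stillness/movement/outing detectors are windowed threshold rules.
Their windows are specified in *seconds* (50 s, 30 s, 10 s — equal to
5000/3000/1000 samples at the 100 Hz collection rate) and converted to
sample counts through the stream's nominal rate, so the same rule
applies unchanged to down-sampled streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as _signal

from .sensor_model import DayRecord, SensorStream, magnitude

# ---------------------------------------------------------------------------
# configuration

#: slot boundaries in hours-of-day: [start, end)
DEFAULT_SLOTS = {
    "morning": (7.0, 10.0),
    "noon": (11.0, 13.0),
    "afternoon": (14.0, 17.0),
    "evening": (17.0, 19.0),
}


@dataclass
class DetectorConfig:
    """Windows and thresholds for the event detectors.

    Windows are in seconds at the nominal sampling rate; search windows
    are ``(start_hour, end_hour)`` pairs.  The light-bedtime search
    wraps midnight: [21:00, 24:00) is scanned before [00:00, 05:00).
    """

    bedtime_window_s: float = 50.0        # 5000 samples @ 100 Hz
    bedtime_tol: float = 2.0
    bedtime_search: tuple = (0.0, 5.0)
    wake_window_s: float = 30.0           # 3000 samples @ 100 Hz
    wake_frac: float = 0.5
    wake_tol: float = 2.0
    wake_search: tuple = (5.0, 12.0)
    outing_light_threshold: float = 1000.0
    outing_accel_window_s: float = 50.0
    outing_accel_frac: float = 0.7
    outing_accel_tol: float = 3.0
    light_bedtime_window_s: float = 10.0  # 1000 samples @ 100 Hz
    light_bedtime_max: float = 1.0
    light_bedtime_search: tuple = (21.0, 5.0)   # wrapped
    activity_tol: float = 2.5
    slots: dict = field(default_factory=lambda: dict(DEFAULT_SLOTS))

    def __post_init__(self):
        for name in ("bedtime_window_s", "wake_window_s",
                     "outing_accel_window_s", "light_bedtime_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("wake_frac", "outing_accel_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        for key in ("bedtime_search", "wake_search", "light_bedtime_search"):
            if key in d:
                d[key] = tuple(d[key])
        if "slots" in d:
            d["slots"] = {k: tuple(v) for k, v in d["slots"].items()}
        return cls(**d)


#: column order of the per-day feature matrix (the 18 features; the IQR
#: family contributes one column per accelerometer axis)
FEATURE_COLUMNS = [
    "aarc", "mean_accel", "gacr", "gyro_gt_0p1_freq", "mean_gyro",
    "mean_light", "light_gt_1000_freq", "iqr_x", "iqr_y", "iqr_z",
    "skewness", "spectral_bandwidth", "spectral_slope",
    "bedtime_accel", "wake_time",
    "out_morning", "out_noon", "out_afternoon", "out_evening",
    "bedtime_light",
]


@dataclass
class FeatureVector:
    """The named per-day feature values; absent detections are NaN."""

    participant_id: str
    date: object
    values: dict

    def as_row(self) -> dict:
        row = {"participant_id": self.participant_id, "date": self.date}
        row.update({c: self.values[c] for c in FEATURE_COLUMNS})
        return row


# ---------------------------------------------------------------------------
# scalar statistics


def aarc(series) -> float:
    """Mean absolute change between consecutive samples.

    Averaging uses n-1, the number of consecutive differences.  The
    same statistic computed on the gyroscope magnitude is the GACR.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("aarc requires at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def mean_value(series) -> float:
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("mean_value requires at least 1 sample")
    return float(np.mean(x))


def exceedance_frequency(series, threshold: float, mode: str = "abs") -> float:
    """Fraction of samples exceeding a threshold.

    ``mode='abs'`` compares |x| > threshold (gyroscope rule);
    ``mode='raw'`` compares x > threshold (light rule).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 1:
        raise ValueError("exceedance_frequency requires at least 1 sample")
    if mode == "abs":
        x = np.abs(x)
    elif mode != "raw":
        raise ValueError("mode must be 'abs' or 'raw'")
    return float(np.mean(x > threshold))


def iqr(series) -> float:
    """Interquartile range under the positional quartile rule.

    Q1 sits at position (n+1)/4 of the sorted series and Q3 at
    3(n+1)/4; a non-integer position takes the mean of the two adjacent
    order statistics.  (This differs from interpolating quantile
    definitions, hence the explicit implementation.)
    """
    x = np.sort(np.asarray(series, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("iqr requires at least 4 samples")

    def at_position(pos: float) -> float:
        if float(pos).is_integer():
            return float(x[int(pos) - 1])
        lo, hi = math.floor(pos), math.ceil(pos)
        return float((x[lo - 1] + x[hi - 1]) / 2.0)

    q1 = at_position((n + 1) / 4.0)
    q3 = at_position(3.0 * (n + 1) / 4.0)
    return q3 - q1


def skewness(series) -> float:
    """Adjusted Fisher-Pearson sample skewness.

    n/((n-1)(n-2)) * sum(((x_i - mean)/s)^3) with s the (n-1) sample
    standard deviation.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("skewness requires at least 3 samples")
    s = np.std(x, ddof=1)
    if s == 0:
        raise ValueError("skewness undefined for a constant series")
    z = (x - np.mean(x)) / s
    return float(n / ((n - 1) * (n - 2)) * np.sum(z ** 3))


def power_spectrum(series, rate: float):
    """Periodogram PSD of the mean-removed series: ``(freqs, power)``."""
    x = np.asarray(series, dtype=float)
    freqs, power = _signal.periodogram(x, fs=rate, detrend="constant")
    return freqs, power


def spectral_moments(freqs, power):
    """Power-weighted mean frequency and spread of a spectrum."""
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(power, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("spectrum carries no power")
    fc = float((f * p).sum() / total)
    bw = float(np.sqrt((((f - fc) ** 2) * p).sum() / total))
    return fc, bw


def spectral_bandwidth(series, rate: float) -> float:
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("spectral_bandwidth requires at least 8 samples")
    return spectral_moments(*power_spectrum(x, rate))[1]


def slope_from_spectrum(freqs, power) -> float:
    """Closed-form OLS slope of P(f) on f.

    slope = (N Σ f P − Σ f Σ P) / (N Σ f² − (Σ f)²)
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(power, dtype=float)
    n = f.size
    if np.unique(f).size < 2:
        raise ValueError("spectral slope requires >= 2 distinct frequencies")
    denom = n * np.sum(f * f) - np.sum(f) ** 2
    return float((n * np.sum(f * p) - np.sum(f) * np.sum(p)) / denom)


def spectral_slope(series, rate: float) -> float:
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("spectral_slope requires at least 8 samples")
    return slope_from_spectrum(*power_spectrum(x, rate))


def activity_duration(accel_mag: SensorStream, tol: float = 2.5) -> float:
    """Minutes of movement: consecutive-sample changes with |Δa| > tol.

    Each exceeding change contributes one sample period (1/rate s).
    """
    a = np.asarray(accel_mag.values, dtype=float)
    if a.size < 2:
        raise ValueError("activity_duration requires at least 2 samples")
    count = int(np.sum(np.abs(np.diff(a)) > tol))
    return count / accel_mag.nominal_rate / 60.0


def meal_time_deviation(times_minutes) -> np.ndarray:
    """Per-day deviation of a participant's meal time from their mean.

    Deviations sum to zero by construction; at least two detected meal
    days are required for the mean to be informative.
    """
    t = np.asarray(times_minutes, dtype=float)
    if t.size < 2:
        raise ValueError("meal_time_deviation requires >= 2 days")
    return t - t.mean()


# ---------------------------------------------------------------------------
# windowed event detectors


def _window_samples(window_s: float, rate: float) -> int:
    w = int(round(window_s * rate))
    return max(w, 1)


def _rolling_sum(flags: np.ndarray, w: int) -> np.ndarray:
    """Sums over every length-w window of a 0/1 array (len = n-w+1)."""
    c = np.concatenate(([0], np.cumsum(flags, dtype=np.int64)))
    return c[w:] - c[:-w]


def _hours(stream: SensorStream, day_start_ms: int) -> np.ndarray:
    return stream.seconds_of_day(day_start_ms) / 3600.0


def _earliest(times_min: np.ndarray):
    return float(times_min.min()) if times_min.size else None


def detect_bedtime_accel(accel_mag: SensorStream, cfg: DetectorConfig,
                         day_start_ms: int):
    """Acceleration-based bedtime: first sustained stillness.

    Returns the earliest time t in the night search window (default
    [00:00, 05:00)) such that every consecutive-sample change in the
    following window stays within ±bedtime_tol, in minutes after
    midnight; ``None`` when no such time exists.
    """
    a = np.asarray(accel_mag.values, dtype=float)
    if a.size < 2:
        return None
    w = _window_samples(cfg.bedtime_window_s, accel_mag.nominal_rate)
    quiet = (np.abs(np.diff(a)) <= cfg.bedtime_tol).astype(np.int8)
    if quiet.size < w:
        return None
    full = _rolling_sum(quiet, w) == w
    hours = _hours(accel_mag, day_start_ms)[: full.size]
    lo, hi = cfg.bedtime_search
    hit = full & (hours >= lo) & (hours < hi)
    return _earliest(hours[hit] * 60.0)


def detect_wakeup(accel_mag: SensorStream, cfg: DetectorConfig,
                  day_start_ms: int):
    """Acceleration-based wake-up: first sustained movement.

    Earliest t in the morning search window whose following window has
    at least ``wake_frac`` of changes with |Δa| >= wake_tol (boundary
    inclusive).  Minutes after midnight, or ``None``.
    """
    a = np.asarray(accel_mag.values, dtype=float)
    if a.size < 2:
        return None
    w = _window_samples(cfg.wake_window_s, accel_mag.nominal_rate)
    moving = (np.abs(np.diff(a)) >= cfg.wake_tol).astype(np.int8)
    if moving.size < w:
        return None
    frac_ok = _rolling_sum(moving, w) >= cfg.wake_frac * w
    hours = _hours(accel_mag, day_start_ms)[: frac_ok.size]
    lo, hi = cfg.wake_search
    hit = frac_ok & (hours >= lo) & (hours < hi)
    return _earliest(hours[hit] * 60.0)


def _outing_accel_ok(accel_mag: SensorStream, cfg: DetectorConfig) -> np.ndarray:
    """Per-change-index flag: following window has >= frac changes > tol."""
    a = np.asarray(accel_mag.values, dtype=float)
    w = _window_samples(cfg.outing_accel_window_s, accel_mag.nominal_rate)
    big = (np.abs(np.diff(a)) > cfg.outing_accel_tol).astype(np.int8)
    if big.size < w:
        return np.zeros(0, dtype=bool)
    return _rolling_sum(big, w) >= cfg.outing_accel_frac * w


def detect_outing(light: SensorStream, accel_mag: SensorStream, slot: str,
                  cfg: DetectorConfig, day_start_ms: int) -> bool:
    """Slot-wise outing detection.

    Morning/noon/afternoon: true iff some time t in the slot has a
    light reading >= 1000 lux and at least 70% of the acceleration
    changes in the following window exceed 3.  Evening: artificial
    lighting makes lux uninformative, so the acceleration condition
    alone decides.
    """
    if slot not in cfg.slots:
        raise ValueError(f"unknown slot {slot!r}")
    lo, hi = cfg.slots[slot]
    accel_ok = _outing_accel_ok(accel_mag, cfg)
    if accel_ok.size == 0:
        return False
    accel_hours = _hours(accel_mag, day_start_ms)[: accel_ok.size]

    if slot == "evening":
        in_slot = (accel_hours >= lo) & (accel_hours < hi)
        return bool(np.any(accel_ok & in_slot))

    light_hours = _hours(light, day_start_ms)
    bright = np.asarray(light.values, dtype=float) >= cfg.outing_light_threshold
    cand = (light_hours >= lo) & (light_hours < hi) & bright
    if not np.any(cand):
        return False
    # align each bright light sample with the acceleration change index
    # starting at (or just after) its timestamp
    idx = np.searchsorted(accel_mag.timestamps, light.timestamps[cand])
    idx = idx[idx < accel_ok.size]
    return bool(np.any(accel_ok[idx]))


def detect_bedtime_light(light: SensorStream, cfg: DetectorConfig,
                         day_start_ms: int):
    """Light-based bedtime: screen goes dark and stays dark.

    Earliest t (searching [21:00, 24:00) then wrapping to [00:00,
    05:00)) such that every light sample in the following window lies
    within [0, light_bedtime_max] lux.  Minutes after midnight, or
    ``None``.
    """
    v = np.asarray(light.values, dtype=float)
    w = _window_samples(cfg.light_bedtime_window_s, light.nominal_rate)
    dark = ((v >= 0) & (v <= cfg.light_bedtime_max)).astype(np.int8)
    if dark.size < w:
        return None
    full = _rolling_sum(dark, w) == w
    hours = _hours(light, day_start_ms)[: full.size]
    start, end = cfg.light_bedtime_search
    late = _earliest(hours[full & (hours >= start)] * 60.0)
    if late is not None:
        return late
    return _earliest(hours[full & (hours < end)] * 60.0)


# ---------------------------------------------------------------------------
# per-day assembly


def extract_feature_vector(day: DayRecord,
                           cfg: DetectorConfig | None = None) -> FeatureVector:
    """Compute the full 18-feature vector for one cleaned participant-day.

    Detector misses (no bedtime / wake found) become NaN; outing
    booleans are encoded 0.0/1.0 so the matrix stays numeric.
    """
    cfg = cfg or DetectorConfig()
    for kind in ("accelerometer", "gyroscope", "light"):
        if kind not in day.streams:
            raise ValueError(f"day is missing the {kind} stream")

    accel = day.streams["accelerometer"]
    gyro = day.streams["gyroscope"]
    light = day.streams["light"]
    a_mag = magnitude(accel)
    g_mag = magnitude(gyro)
    start = day.day_start_ms

    v: dict = {}
    v["aarc"] = aarc(a_mag.values)
    v["mean_accel"] = mean_value(a_mag.values)
    v["gacr"] = aarc(g_mag.values)
    v["gyro_gt_0p1_freq"] = exceedance_frequency(g_mag.values, 0.1, "abs")
    v["mean_gyro"] = mean_value(g_mag.values)
    v["mean_light"] = mean_value(light.values)
    v["light_gt_1000_freq"] = exceedance_frequency(
        light.values, cfg.outing_light_threshold, "raw")
    for i, axis in enumerate("xyz"):
        v[f"iqr_{axis}"] = iqr(accel.values[:, i])
    # a perfectly still day has zero variance / zero power: the shape
    # statistics are undefined there and recorded as missing (the
    # explicit constancy check avoids float round-off masquerading as
    # variance on long constant series)
    if np.all(a_mag.values == a_mag.values[0]):
        v["skewness"] = np.nan
        v["spectral_bandwidth"] = np.nan
        v["spectral_slope"] = np.nan
    else:
        try:
            v["skewness"] = skewness(a_mag.values)
        except ValueError:
            v["skewness"] = np.nan
        v["spectral_bandwidth"] = spectral_bandwidth(
            a_mag.values, a_mag.nominal_rate)
        v["spectral_slope"] = spectral_slope(a_mag.values, a_mag.nominal_rate)

    bt = detect_bedtime_accel(a_mag, cfg, start)
    v["bedtime_accel"] = np.nan if bt is None else bt
    wk = detect_wakeup(a_mag, cfg, start)
    v["wake_time"] = np.nan if wk is None else wk
    for slot in ("morning", "noon", "afternoon", "evening"):
        v[f"out_{slot}"] = float(detect_outing(light, a_mag, slot, cfg, start))
    lt = detect_bedtime_light(light, cfg, start)
    v["bedtime_light"] = np.nan if lt is None else lt

    return FeatureVector(day.participant_id, day.date, v)


def feature_matrix(days, cfg: DetectorConfig | None = None):
    """Stack per-day vectors into a tidy DataFrame (one row per day)."""
    import pandas as pd

    rows = [extract_feature_vector(d, cfg).as_row() for d in days]
    return pd.DataFrame(rows)
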