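"""Sensor stream data model, log parsing, and cleaning.

The raw input is a time-stamped sensor log in a simple CSV dialect
(header ``participant_id,timestamp_ms,sensor,x,y,z``): one row per
sample, epoch-millisecond timestamps, three axis columns for the
accelerometer (m/s^2) and gyroscope (rad/s), and a single lux value in
``x`` for the ambient-light sensor.  A companion PHQ-9 CSV
(``participant_id,administration_date,q1..q9``) carries the screening
labels.

Cleaning mirrors a typical field campaign: malformed rows are dropped
and counted, samples are grouped into participant-days, and days whose
per-sensor sample coverage falls below a configurable fraction of the
nominal rate are discarded as insufficient for analysis.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

import numpy as np
import pandas as pd

SENSOR_KINDS = ("accelerometer", "gyroscope", "light")

#: seconds in the local day window [00:00, 24:00)
DAY_SECONDS = 86400

_LOG_HEADER = "participant_id,timestamp_ms,sensor,x,y,z"

# one well-formed log row: id, integer ms, known sensor, numeric axes
# (light: x only, y and z empty)
_ROW_RE = re.compile(
    r"^(?P<pid>[A-Za-z0-9_\-]+),"
    r"(?P<ts>\d+),"
    r"(?P<sensor>accelerometer|gyroscope|light),"
    r"(?P<x>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?),"
    r"(?P<y>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?,"
    r"(?P<z>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)?$"
)


@dataclass
class SensorStream:
    """Uniformly sampled series for one sensor on one participant-day.

    ``values`` is ``(n,)`` for light (lux) and ``(n, 3)`` for the
    accelerometer and gyroscope.  Timestamps are epoch milliseconds,
    strictly increasing.
    """

    sensor_kind: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValueError(f"unknown sensor kind {self.sensor_kind!r}")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sensor_kind == "light" and np.any(self.values < 0):
            raise ValueError("light values must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    def seconds_of_day(self, day_start_ms: int) -> np.ndarray:
        """Sample times as float seconds after local midnight."""
        return (self.timestamps - day_start_ms) / 1000.0


@dataclass
class DayRecord:
    """All sensor streams for one participant on one calendar day."""

    participant_id: str
    date: date
    streams: dict[str, SensorStream] = field(default_factory=dict)

    @property
    def day_start_ms(self) -> int:
        dt = datetime(self.date.year, self.date.month, self.date.day,
                      tzinfo=timezone.utc)
        return int(dt.timestamp() * 1000)


@dataclass
class CleaningReport:
    lines_read: int = 0
    lines_dropped_malformed: int = 0
    days_dropped_insufficient: int = 0
    retained_records: list[DayRecord] = field(default_factory=list)


def magnitude(stream: SensorStream) -> SensorStream:
    """Per-sample Euclidean norm of a 3-axis stream.

    The detectors and rate-of-change features operate on a scalar
    acceleration (or angular-rate) series; this collapses the three
    axes to their vector magnitude, leaving timestamps untouched.
    """
    if stream.sensor_kind == "light":
        raise ValueError("magnitude is defined for 3-axis streams only")
    vals = np.linalg.norm(stream.values, axis=1)
    return SensorStream(stream.sensor_kind, stream.timestamps, vals,
                        stream.nominal_rate)


def _day_start_ms(ts_ms: int) -> int:
    return int(ts_ms - ts_ms % (DAY_SECONDS * 1000))


def parse_sensor_log(lines, expected_rate: float):
    """Parse raw log lines into day records.

    Malformed lines (wrong field count, unknown sensor, non-numeric
    values) are dropped and counted.  Samples are grouped by
    participant, UTC calendar day, and sensor; within each group
    timestamps are sorted and duplicate timestamps collapse to the
    first occurrence.

    Returns ``(records, CleaningReport)``.  Empty input yields an empty
    record list and a zero-count report.
    """
    rows = []
    report = CleaningReport()
    for raw in lines:
        line = raw.rstrip("\n")
        if not line or line == _LOG_HEADER:
            continue
        report.lines_read += 1
        m = _ROW_RE.match(line)
        if m is None:
            report.lines_dropped_malformed += 1
            continue
        sensor = m.group("sensor")
        y, z = m.group("y"), m.group("z")
        if sensor == "light":
            if y not in (None, "") or z not in (None, ""):
                report.lines_dropped_malformed += 1
                continue
            vec = (float(m.group("x")), 0.0, 0.0)
            if vec[0] < 0:
                report.lines_dropped_malformed += 1
                continue
        else:
            if y in (None, "") or z in (None, ""):
                report.lines_dropped_malformed += 1
                continue
            vec = (float(m.group("x")), float(y), float(z))
        rows.append((m.group("pid"), int(m.group("ts")), sensor, *vec))

    records: list[DayRecord] = []
    if not rows:
        return records, report

    df = pd.DataFrame(rows, columns=["pid", "ts", "sensor", "x", "y", "z"])
    df["day_ms"] = df["ts"] - df["ts"] % (DAY_SECONDS * 1000)
    for (pid, day_ms), day_df in df.groupby(["pid", "day_ms"], sort=True):
        rec = DayRecord(
            participant_id=str(pid),
            date=datetime.fromtimestamp(day_ms / 1000, tz=timezone.utc).date(),
        )
        for sensor, s_df in day_df.groupby("sensor", sort=True):
            s_df = s_df.sort_values("ts", kind="stable")
            s_df = s_df.drop_duplicates("ts", keep="first")
            ts = s_df["ts"].to_numpy(np.int64)
            if sensor == "light":
                vals = s_df["x"].to_numpy(float)
            else:
                vals = s_df[["x", "y", "z"]].to_numpy(float)
            rec.streams[sensor] = SensorStream(sensor, ts, vals, expected_rate)
        records.append(rec)
    report.retained_records = records
    return records, report


def serialize_sensor_log(records) -> str:
    """Write day records back to the log CSV dialect (round-trippable)."""
    buf = io.StringIO()
    buf.write(_LOG_HEADER + "\n")
    for rec in records:
        for kind in SENSOR_KINDS:
            stream = rec.streams.get(kind)
            if stream is None:
                continue
            if kind == "light":
                for t, v in zip(stream.timestamps, stream.values):
                    buf.write(f"{rec.participant_id},{t},{kind},{float(v)!r},,\n")
            else:
                for t, v in zip(stream.timestamps, stream.values):
                    buf.write(f"{rec.participant_id},{t},{kind},"
                              f"{float(v[0])!r},{float(v[1])!r},{float(v[2])!r}\n")
    return buf.getvalue()


def drop_insufficient_days(records, min_coverage: float = 0.5):
    """Remove days whose sample coverage is too low for analysis.

    A day is retained iff every one of the three sensors is present and
    has at least ``min_coverage * nominal_rate * 86400`` samples.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    report = CleaningReport()
    kept = []
    for rec in records:
        ok = True
        for kind in SENSOR_KINDS:
            stream = rec.streams.get(kind)
            if stream is None:
                ok = False
                break
            required = min_coverage * stream.nominal_rate * DAY_SECONDS
            if len(stream) < required:
                ok = False
                break
        if ok:
            kept.append(rec)
        else:
            report.days_dropped_insufficient += 1
    report.retained_records = kept
    return kept, report


def read_phq9_csv(text: str) -> pd.DataFrame:
    """Read the PHQ-9 CSV dialect into a tidy frame.

    Columns: participant_id, administration_date, q1..q9 (ints 0-3).
    """
    df = pd.read_csv(io.StringIO(text))
    expected = ["participant_id", "administration_date"] + [f"q{i}" for i in range(1, 10)]
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"PHQ-9 CSV missing columns: {sorted(missing)}")
    return df[expected]
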