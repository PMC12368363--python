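"""Synthetic smartphone-sensor cohorts with severity-coupled behavior.

Real passive-sensing cohorts are small and private, so every stage of
the pipeline is exercised on simulated participant-days instead.  Each
participant gets a :class:`BehavioralProfile` whose parameters co-vary
with a latent PHQ-9-scale severity in the directions reported for
campus cohorts: higher severity means a later and more variable
bedtime, a shorter night, fewer (especially evening) outings, more
irregular meal times, and less physical activity.

A day is laid out on a minute grid as behavioral segments — pre-sleep
phone use, sleep, a wake-up stir, indoor sedentary time, movement
bouts, and slot-bound outings — then rendered into 3-axis
accelerometer (m/s^2), 3-axis gyroscope (rad/s) and scalar light (lux)
streams at a configurable rate.  Segment noise levels are chosen so
the windowed detectors in :mod:`phonesense.features` recover the
scheduled events: sleep keeps |Δa| well inside ±2 and lux in [0, 1];
outings hold lux above 1000 (except in the evening, when lighting is
uninformative) with most |Δa| above 3; movement bouts carry gyroscope
magnitudes above 0.1 rad/s.

The generator does not attempt to reproduce any real cohort's exact
distributions — only the directions and detector thresholds above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .phq9 import PHQ9Record
from .sensor_model import DayRecord, SensorStream
from . import features as _features

# severity-coupling multipliers for the three presets
COUPLING_SCALE = {"none": 0.0, "default": 1.0, "strong": 1.5}

# gravitational baseline for the accelerometer magnitude, m/s^2
_G = 9.8

# minute-grid segment kinds
_SLEEP, _PRESLEEP, _INDOOR, _STIR, _BOUT, _OUTING, _OUTING_DARK = range(7)
_KIND_NAMES = {
    _SLEEP: "sleep", _PRESLEEP: "presleep-use", _INDOOR: "indoor-sedentary",
    _STIR: "wake-stir", _BOUT: "movement-bout", _OUTING: "outing",
    _OUTING_DARK: "outing-dark",
}

# nominal slot meal/outing centers, minutes after midnight
_SLOT_CENTERS = {"morning": 510, "noon": 720, "afternoon": 930, "evening": 1080}

# movement bouts keep clear of 16:45-19:05 so the accelerometer-only
# evening-outing rule fires only for scheduled evening outings
_EVENING_GUARD = (1005, 1145)

_STIR_MINUTES = 10
_OUTING_MINUTES = 25
_BOUT_MINUTES = 15


@dataclass
class BehavioralProfile:
    """Per-participant behavioral parameters tied to a latent severity."""

    participant_id: str
    severity: float                      # PHQ-9 scale, [0, 27]
    bedtime_mean: float                  # minutes after midnight
    bedtime_sd: float
    wake_mean: float
    wake_sd: float
    outing_prob: dict                    # slot -> probability
    meal_time_sd: float                  # minutes
    activity_amplitude: float            # m/s^2 scale of movement bursts
    daily_activity_minutes: float

    def __post_init__(self):
        if not 0 <= self.severity <= 27:
            raise ValueError("severity must lie in [0, 27]")
        if any(not 0 <= p <= 1 for p in self.outing_prob.values()):
            raise ValueError("outing probabilities must lie in [0, 1]")
        for name in ("bedtime_sd", "wake_sd", "meal_time_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class DaySchedule:
    """Ground-truth behavioral layout of one generated day."""

    segments: list                       # (start_min, end_min, kind name)
    bedtime_minutes: float
    wake_minutes: float
    outings: dict                        # slot -> bool
    outing_times: dict                   # slot -> start minute or None
    bout_minutes: float


def sample_profile(severity: float, seed: int,
                   coupling: str = "default") -> BehavioralProfile:
    """Draw one participant profile for a given severity.

    Deterministic for a given (severity, seed, coupling).  At severity
    0 the expected bedtime sits at 00:21 — the regular-sleeper anchor —
    and drifts later (with growing spread) as severity rises; evening
    outings and activity shrink with severity, since the dinner slot is
    where outing behavior separates most.
    """
    if not 0 <= severity <= 27:
        raise ValueError("severity must lie in [0, 27]")
    scale = COUPLING_SCALE[coupling]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    sev = scale * severity / 27.0

    def jitter(sd):
        return float(rng.normal(0.0, sd))

    outing_prob = {
        "morning": float(np.clip(0.70 - 0.35 * sev + jitter(0.03), 0.02, 0.98)),
        "noon": float(np.clip(0.92 - 0.15 * sev + jitter(0.03), 0.02, 0.98)),
        "afternoon": float(np.clip(0.60 - 0.25 * sev + jitter(0.03), 0.02, 0.98)),
        "evening": float(np.clip(0.90 - 0.60 * sev + jitter(0.03), 0.02, 0.98)),
    }
    return BehavioralProfile(
        participant_id="",
        severity=float(severity),
        bedtime_mean=21.0 + 120.0 * sev + jitter(8.0),
        bedtime_sd=max(1.0, 5.0 + 40.0 * sev + jitter(2.0)),
        wake_mean=450.0 + 60.0 * sev + jitter(10.0),
        wake_sd=max(1.0, 8.0 + 15.0 * sev + jitter(2.0)),
        outing_prob=outing_prob,
        meal_time_sd=max(1.0, 6.0 + 25.0 * sev + jitter(1.0)),
        activity_amplitude=float(max(0.3, 3.0 - 1.8 * sev + jitter(0.1))),
        daily_activity_minutes=float(max(10.0, 90.0 - 55.0 * sev + jitter(5.0))),
    )


# ---------------------------------------------------------------------------
# day layout


def _layout_day(profile: BehavioralProfile, rng, slots) -> tuple:
    """Sample one day's minute grid and its ground-truth schedule."""
    grid = np.full(1440, _INDOOR, dtype=np.int8)

    b = float(np.clip(rng.normal(profile.bedtime_mean, profile.bedtime_sd),
                      5.0, 285.0))
    w = float(np.clip(rng.normal(profile.wake_mean, profile.wake_sd),
                      max(312.0, b + 90.0), 690.0))
    bi, wi = int(round(b)), int(round(w))
    grid[:bi] = _PRESLEEP
    grid[bi:wi] = _SLEEP
    grid[wi:wi + _STIR_MINUTES] = _STIR

    outings: dict = {}
    outing_times: dict = {}
    for slot, (lo_h, hi_h) in slots.items():
        lo, hi = lo_h * 60.0, hi_h * 60.0
        wanted = rng.random() < profile.outing_prob[slot]
        start_lo = max(lo + 2.0, w + _STIR_MINUTES + 5.0)
        start_hi = hi - _OUTING_MINUTES - 2.0
        if not wanted or start_lo > start_hi:
            outings[slot] = False
            outing_times[slot] = None
            continue
        t0 = float(np.clip(
            rng.normal(_SLOT_CENTERS[slot], profile.meal_time_sd),
            start_lo, start_hi))
        i0 = int(round(t0))
        kind = _OUTING_DARK if slot == "evening" else _OUTING
        grid[i0:i0 + _OUTING_MINUTES] = kind
        outings[slot] = True
        outing_times[slot] = t0

    # movement bouts on free indoor minutes, clear of the evening guard
    target = profile.daily_activity_minutes
    placed = 0.0
    candidates = np.flatnonzero(grid == _INDOOR)
    candidates = candidates[(candidates >= wi + _STIR_MINUTES)
                            & (candidates < 1380)
                            & ((candidates + _BOUT_MINUTES <= _EVENING_GUARD[0])
                               | (candidates >= _EVENING_GUARD[1]))]
    rng.shuffle(candidates)
    for start in candidates:
        if placed >= target:
            break
        seg = grid[start:start + _BOUT_MINUTES]
        if np.all(seg == _INDOOR):
            grid[start:start + _BOUT_MINUTES] = _BOUT
            placed += _BOUT_MINUTES

    segments = []
    edges = np.flatnonzero(np.diff(grid)) + 1
    bounds = np.concatenate(([0], edges, [1440]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        segments.append((int(s), int(e), _KIND_NAMES[int(grid[s])]))

    schedule = DaySchedule(segments=segments, bedtime_minutes=b,
                           wake_minutes=w, outings=outings,
                           outing_times=outing_times, bout_minutes=placed)
    return grid, schedule


# ---------------------------------------------------------------------------
# stream rendering


def _mixture(rng, n, p_hi, lo_rng, hi_rng):
    """n draws: with prob p_hi from hi_rng uniform, else lo_rng uniform."""
    hi = rng.random(n) < p_hi
    out = rng.uniform(*lo_rng, n)
    out[hi] = rng.uniform(*hi_rng, int(hi.sum()))
    return out


def _accel_step_magnitudes(rng, kinds, amp):
    """Per-sample deviation magnitude; |Δa| ≈ mean of adjacent magnitudes."""
    m = np.empty(kinds.size)
    for kind, mask in _kind_masks(kinds):
        n = int(mask.sum())
        if n == 0:
            continue
        if kind == _SLEEP:
            m[mask] = np.abs(rng.normal(0.0, 0.12, n))
        elif kind == _PRESLEEP:
            # in-bed phone handling: restless enough that stillness
            # detectors never fire (|Δa| > 2) yet below the physical-
            # activity threshold (|Δa| < 2.5)
            m[mask] = rng.uniform(2.1, 2.4, n)
        elif kind == _INDOOR:
            m[mask] = _mixture(rng, n, 0.10, (0.0, 1.5), (1.5, 2.8))
        elif kind == _STIR:
            m[mask] = rng.uniform(2.0, 2.9, n)
        elif kind == _BOUT:
            m[mask] = _mixture(rng, n, 0.85, (0.5, 2.0), (2.6, 2.6 + amp))
        else:  # outings
            m[mask] = _mixture(rng, n, 0.92, (0.0, 1.5), (3.3, 3.3 + amp))
    return m


def _kind_masks(kinds):
    for kind in range(7):
        yield kind, kinds == kind


def _render_streams(grid, profile, rate, rng, day_start_ms):
    spm = int(round(rate * 60))
    if abs(spm - rate * 60) > 1e-9 or spm < 1:
        raise ValueError("rate must give an integer number of samples/minute")
    kinds = np.repeat(grid, spm)
    n = kinds.size
    step_ms = round(60000 / spm)
    ts = day_start_ms + np.arange(n, dtype=np.int64) * step_ms

    # accelerometer: alternating-sign deviations around gravity so that
    # consecutive-sample changes track the per-segment magnitude scale
    m = _accel_step_magnitudes(rng, kinds, profile.activity_amplitude)
    sign = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    r = _G + sign * m / 2.0
    dx = rng.normal(0.0, 0.25, n)
    dy = rng.normal(0.0, 0.25, n)
    norm = np.sqrt(dx * dx + dy * dy + 1.0)
    accel = np.column_stack((r * dx / norm, r * dy / norm, r / norm))

    # gyroscope: bursts above 0.1 rad/s during movement, quiet otherwise
    active = np.isin(kinds, (_STIR, _BOUT, _OUTING, _OUTING_DARK))
    omega = rng.uniform(0.0, 0.08, n)
    n_act = int(active.sum())
    omega[active] = rng.uniform(
        0.12, 0.12 + 0.4 * profile.activity_amplitude, n_act)
    gdir = rng.normal(size=(n, 3))
    gdir /= np.linalg.norm(gdir, axis=1, keepdims=True)
    gyro = omega[:, None] * gdir

    # light: screen-off sleep in [0, 1); daylit outings above 1000 lux
    light = np.empty(n)
    for kind, mask in _kind_masks(kinds):
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        if kind == _SLEEP:
            light[mask] = rng.uniform(0.0, 0.9, cnt)
        elif kind == _PRESLEEP:
            light[mask] = rng.uniform(2.0, 40.0, cnt)
        elif kind == _OUTING:
            light[mask] = rng.uniform(1200.0, 12000.0, cnt)
        else:  # indoor daytime, bouts, stir, dark evening outing
            light[mask] = rng.uniform(120.0, 900.0, cnt)

    return {
        "accelerometer": SensorStream("accelerometer", ts, accel, rate),
        "gyroscope": SensorStream("gyroscope", ts, gyro, rate),
        "light": SensorStream("light", ts, light, rate),
    }


def generate_day(profile: BehavioralProfile, rate: float, seed,
                 day_date: date = date(2024, 1, 1),
                 cfg: "_features.DetectorConfig | None" = None):
    """Render one participant-day: ``(DayRecord, DaySchedule)``.

    Reproducible for a given (profile, rate, seed).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    cfg = cfg or _features.DetectorConfig()
    rng = np.random.default_rng(seed)
    grid, schedule = _layout_day(profile, rng, cfg.slots)
    record = DayRecord(participant_id=profile.participant_id or "anon",
                       date=day_date)
    record.streams = _render_streams(grid, profile, rate, rng,
                                     record.day_start_ms)
    return record, schedule


# ---------------------------------------------------------------------------
# cohorts


def default_severity_sampler(rng, index: int) -> int:
    """Paper-scale class mix: 5 of every 12 participants score below 5."""
    if index % 12 < 5:
        return int(rng.integers(0, 5))
    return int(rng.integers(5, 28))


def _phq9_items(rng, severity: float):
    """One administration: 9 items in {0..3} whose total tracks severity."""
    total = int(np.clip(round(rng.normal(severity, 1.2)), 0, 27))
    base, rem = divmod(total, 9)
    items = np.full(9, base, dtype=int)
    bump = rng.choice(9, size=rem, replace=False)
    items[bump] += 1
    return items.tolist()


def iter_cohort_days(n_participants: int, days_per_participant: int,
                     severity_sampler=None, rate: float = 1.0, seed=0,
                     coupling: str = "default",
                     cfg: "_features.DetectorConfig | None" = None):
    """Yield ``(profile, day_index, DayRecord, DaySchedule)`` lazily.

    Memory-light companion to :func:`generate_cohort`: raw streams can
    be discarded as soon as each day's features are extracted.
    """
    if n_participants < 1 or days_per_participant < 1:
        raise ValueError("counts must be >= 1")
    sampler = severity_sampler or default_severity_sampler
    root = np.random.SeedSequence(int(seed))
    sev_rng = np.random.default_rng(root.spawn(1)[0])
    start = date(2024, 1, 1)
    for i in range(n_participants):
        pseed = root.spawn(1)[0]
        severity = sampler(sev_rng, i)
        profile = sample_profile(severity, pseed.generate_state(1)[0] % (2**31),
                                 coupling)
        profile.participant_id = f"p{i + 1:02d}"
        for d in range(days_per_participant):
            record, schedule = generate_day(
                profile, rate, pseed.spawn(1)[0],
                day_date=start + timedelta(days=d), cfg=cfg)
            yield profile, d, record, schedule


def generate_phq9(profile: BehavioralProfile, n_days: int, rng,
                  every: int = 3) -> PHQ9Record:
    """Administrations every ``every`` days, totals near the severity."""
    admins = []
    start = date(2024, 1, 1)
    for d in range(0, n_days, every):
        admins.append(((start + timedelta(days=d)).isoformat(),
                       _phq9_items(rng, profile.severity)))
    return PHQ9Record(participant_id=profile.participant_id,
                      administrations=admins)


def generate_cohort(n_participants: int, days_per_participant: int,
                    severity_sampler=None, rate: float = 1.0, seed=0,
                    coupling: str = "default"):
    """Materialize a full cohort: ``(DayRecord list, PHQ9Record list)``.

    At 1 Hz a 12x11-day cohort holds ~34M samples; for larger runs use
    :func:`iter_cohort_days` and extract features incrementally.
    """
    records, phq = [], []
    phq_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9]))
    seen = {}
    for profile, d, record, _ in iter_cohort_days(
            n_participants, days_per_participant, severity_sampler,
            rate, seed, coupling):
        records.append(record)
        if profile.participant_id not in seen:
            seen[profile.participant_id] = profile
            phq.append(generate_phq9(profile, days_per_participant, phq_rng))
    return records, phq


def cohort_feature_matrix(n_participants: int, days_per_participant: int,
                          severity_sampler=None, rate: float = 1.0, seed=0,
                          coupling: str = "default",
                          cfg: "_features.DetectorConfig | None" = None,
                          with_phq9: bool = False):
    """Generate a cohort and extract per-day features incrementally.

    Raw streams are discarded day by day, so arbitrarily large cohorts
    fit in memory.  Returns ``(features DataFrame, severities
    DataFrame, schedules)``: one feature row per day (the 18 feature
    columns plus the derived ``activity_minutes``), one latent severity
    per participant, and the ground-truth schedules keyed
    ``(participant_id, day_index)``.  With ``with_phq9=True`` a fourth
    element carries the simulated PHQ-9 records (identical to what
    :func:`generate_cohort` produces for the same seed).
    """
    import pandas as pd

    from .sensor_model import magnitude

    cfg = cfg or _features.DetectorConfig()
    rows, schedules, sev = [], {}, {}
    profiles = {}
    for profile, d, record, schedule in iter_cohort_days(
            n_participants, days_per_participant, severity_sampler,
            rate, seed, coupling, cfg):
        row = _features.extract_feature_vector(record, cfg).as_row()
        row["activity_minutes"] = _features.activity_duration(
            magnitude(record.streams["accelerometer"]), cfg.activity_tol)
        rows.append(row)
        schedules[(profile.participant_id, d)] = schedule
        sev[profile.participant_id] = profile.severity
        profiles.setdefault(profile.participant_id, profile)
    feats = pd.DataFrame(rows)
    severities = pd.DataFrame(
        {"participant_id": list(sev), "severity": list(sev.values())})
    if not with_phq9:
        return feats, severities, schedules
    phq_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9]))
    phq = [generate_phq9(p, days_per_participant, phq_rng)
           for p in profiles.values()]
    return feats, severities, schedules, phq
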