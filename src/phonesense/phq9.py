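"""PHQ-9 scoring, severity banding, aggregation, and label binarization.

The nine-item Patient Health Questionnaire scores each item 0-3 for a
total of 0-27.  Severity bands: below 5 none, 5-9 mild, 10-14
moderate, 15-19 moderately severe, 20 and above severe.  Repeated
administrations (every 3 days in this protocol) are averaged into one
score per participant; participants whose totals swing by more than a
consistency threshold are excluded as unreliable raters.  For
classification the averaged score is binarized at the screening cutoff
of 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEVERITY_BANDS = (
    (0, 5, "none"),
    (5, 10, "mild"),
    (10, 15, "moderate"),
    (15, 20, "moderately-severe"),
    (20, 28, "severe"),
)

#: screening cutoff: scores >= 5 are labeled positive
BINARY_CUTOFF = 5

#: default tolerance (in points) for between-administration consistency;
#: one severity band's width
DEFAULT_CONSISTENCY_THRESHOLD = 5


@dataclass
class PHQ9Record:
    participant_id: str
    administrations: list = field(default_factory=list)  # (date, [9 items])
    aggregated_score: float | None = None
    excluded: bool = False

    @property
    def totals(self) -> list:
        return [score_administration(items) for _, items in self.administrations]


def score_administration(items) -> int:
    """Total score of one administration: the sum of the 9 item scores."""
    items = list(items)
    if len(items) != 9:
        raise ValueError(f"expected 9 item scores, got {len(items)}")
    for it in items:
        if int(it) != it or not 0 <= int(it) <= 3:
            raise ValueError(f"item score {it!r} outside {{0,1,2,3}}")
    return int(sum(int(i) for i in items))


def severity_band(total: float) -> str:
    if not 0 <= total <= 27:
        raise ValueError(f"PHQ-9 total {total} outside [0, 27]")
    for lo, hi, name in SEVERITY_BANDS:
        if lo <= total < hi:
            return name
    raise AssertionError("unreachable")


def aggregate_administrations(
    record: PHQ9Record,
    consistency_threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
) -> PHQ9Record:
    """Average repeated administrations into one score.

    The participant is excluded (no aggregated score) when the spread
    of their totals, max - min, exceeds the consistency threshold.
    """
    totals = record.totals
    if not totals:
        raise ValueError("record has no administrations")
    if max(totals) - min(totals) > consistency_threshold:
        record.excluded = True
        record.aggregated_score = None
    else:
        record.excluded = False
        record.aggregated_score = sum(totals) / len(totals)
    return record


def binarize_label(aggregated_score: float) -> int:
    """1 iff the (possibly fractional) score reaches the cutoff of 5."""
    if not 0 <= aggregated_score <= 27:
        raise ValueError(f"score {aggregated_score} outside [0, 27]")
    return int(aggregated_score >= BINARY_CUTOFF)


def records_from_frame(df) -> list:
    """Group a tidy PHQ-9 frame (see sensor_model) into PHQ9Record objects."""
    out = []
    qcols = [f"q{i}" for i in range(1, 10)]
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("administration_date", kind="stable")
        admins = [(row["administration_date"], [int(row[q]) for q in qcols])
                  for _, row in g.iterrows()]
        out.append(PHQ9Record(participant_id=str(pid), administrations=admins))
    return out
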