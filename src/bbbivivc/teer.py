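"""Blank correction, area normalization and time-course summarization of
transendothelial electrical resistance (TEER) readings.

Raw chopstick-electrode resistance includes the cell-free insert and medium;
the standard correction subtracts the mean blank-insert resistance of the
same day, then multiplies by membrane area to give Ω·cm².  Negative
corrected values are preserved and flagged — clamping them to zero would
hide electrode drift and failed monolayers.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import QcFlag, TeerRecord, TeerValue

__all__ = [
    "NormalizedTeer",
    "normalize_teer",
    "blank_means",
    "normalize_records",
    "summarize_timecourse",
    "select_assay_day",
]


@dataclass(frozen=True)
class NormalizedTeer:
    """One blank-corrected, area-normalized TEER value (Ω·cm²) with QC flags."""

    model_id: str
    insert_id: str
    day: int
    value: float
    flags: frozenset = field(default_factory=frozenset)


def normalize_teer(record: TeerRecord, blank_mean: float) -> NormalizedTeer:
    """Blank-correct and area-normalize one resistance reading.

    Returns (resistance − blank_mean) × membrane_area in Ω·cm².  A reading
    at or below the blank yields a zero or negative value carrying a QC
    flag instead of raising.
    """
    if record.is_blank:
        raise ValueError("cannot normalize a blank insert against blanks")
    if blank_mean <= 0:
        raise ValueError("blank_mean must be positive")
    value = (record.resistance_raw - blank_mean) * record.membrane_area
    flags = set()
    if record.resistance_raw <= blank_mean:
        flags.add(QcFlag.LOW_BARRIER)
    if value < 0:
        flags.add(QcFlag.NEGATIVE_TEER)
    return NormalizedTeer(
        model_id=record.model_id,
        insert_id=record.insert_id,
        day=record.day,
        value=value,
        flags=frozenset(flags),
    )


def blank_means(records: Iterable[TeerRecord]) -> dict[int, float]:
    """Mean blank-insert resistance (Ω) per day."""
    by_day: dict[int, list[float]] = defaultdict(list)
    for rec in records:
        if rec.is_blank:
            by_day[rec.day].append(rec.resistance_raw)
    return {day: float(np.mean(vals)) for day, vals in by_day.items()}


def normalize_records(records: Sequence[TeerRecord]) -> list[NormalizedTeer]:
    """Normalize every non-blank record against its day's mean blank."""
    blanks = blank_means(records)
    if not blanks:
        raise ValueError("no blank inserts found; cannot blank-correct")
    out = []
    for rec in records:
        if rec.is_blank:
            continue
        if rec.day not in blanks:
            raise ValueError(f"no blank reading for day {rec.day}")
        out.append(normalize_teer(rec, blanks[rec.day]))
    return out


def _sem(values: np.ndarray) -> float:
    # sample SD (n−1) over √n; zero for a single replicate
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def summarize_timecourse(values: Sequence[NormalizedTeer]) -> list[TeerValue]:
    """Per-(model, day) mean ± SEM of corrected TEER, ordered by model then day.

    Row order of the input is irrelevant; groups inherit the union of their
    members' QC flags.
    """
    if not values:
        raise ValueError("no TEER values to summarize")
    groups: dict[tuple[str, int], list[NormalizedTeer]] = defaultdict(list)
    for v in values:
        groups[(v.model_id, v.day)].append(v)
    out = []
    for (model_id, day) in sorted(groups):
        members = groups[(model_id, day)]
        arr = np.array([m.value for m in members], dtype=float)
        flags: set = set()
        for m in members:
            flags |= m.flags
        out.append(
            TeerValue(
                model_id=model_id,
                day=day,
                teer_mean=float(arr.mean()),
                teer_sem=_sem(arr),
                n=arr.size,
                flags=frozenset(flags),
            )
        )
    return out


def select_assay_day(
    timecourse: Sequence[TeerValue], window: tuple[int, int] | None = None
) -> int:
    """Day with the maximal mean TEER inside ``window`` (inclusive).

    Ties break toward the earlier day, favoring shorter culture time.
    Values from multiple models on the same day are averaged first.
    """
    if not timecourse:
        raise ValueError("empty timecourse")
    by_day: dict[int, list[float]] = defaultdict(list)
    for v in timecourse:
        by_day[v.day].append(v.teer_mean)
    days = sorted(by_day)
    if window is None:
        window = (days[0], days[-1])
    lo, hi = window
    if lo > hi:
        raise ValueError("empty window")
    candidates = [d for d in days if lo <= d <= hi]
    if not candidates:
        raise ValueError(f"window {window} not covered by timecourse days {days}")
    # max() keeps the first maximal element → earliest day wins ties
    return max(candidates, key=lambda d: (float(np.mean(by_day[d])), -d))
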