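"""Descriptive tabulations of deaths, injuries and detentions.

Frequency tables over any schema field, with the denominator always stated
explicitly: either all records (unknowns shown as their own category) or
known values only (unknowns removed from the denominator). Percentages round
to the nearest integer, halves away from zero.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import round_half_up
from .records import LinkedPerson, RawRecord

__all__ = ["FrequencyTable", "tabulate", "tabulate_detentions", "deadliest_day"]

_TABULATABLE_FIELDS = (
    "source_id",
    "record_kind",
    "gender",
    "age_years",
    "minor_flag",
    "event_date",
    "place",
    "cause",
    "gunshot_site",
    "role",
)

_UNKNOWN = {None, "unknown"}


@dataclass(frozen=True)
class FrequencyTable:
    """Counts and percentages of one field over a stated denominator."""

    dimension: str
    rows: tuple[tuple[object, int, int], ...]  # (category, count, percent)
    denominator: int
    known_only: bool

    def count(self, category) -> int:
        for cat, cnt, _ in self.rows:
            if cat == category:
                return cnt
        return 0

    def percent(self, category) -> int:
        for cat, _, pct in self.rows:
            if cat == category:
                return pct
        raise KeyError(category)

    def __str__(self) -> str:
        head = (
            f"{self.dimension} (n = {self.denominator}"
            + (", known values only)" if self.known_only else ", all records)")
        )
        lines = [head]
        for cat, cnt, pct in self.rows:
            lines.append(f"  {cat}: {cnt} ({pct}%)")
        return "\n".join(lines)


def tabulate(
    records: Sequence[RawRecord | LinkedPerson],
    dimension: str,
    known_only: bool = True,
) -> FrequencyTable:
    """Frequency table of *dimension* over *records*.

    With ``known_only`` the denominator is restricted to records whose value
    is known; otherwise unknowns appear as an ``"unknown"`` category and the
    denominator is every record.
    """
    if dimension not in _TABULATABLE_FIELDS:
        raise ValueError(
            f"unknown field {dimension!r}; valid fields: {', '.join(_TABULATABLE_FIELDS)}"
        )
    values = []
    for r in records:
        v = getattr(r, dimension)
        if v in _UNKNOWN:
            if known_only:
                continue
            v = "unknown"
        values.append(v)
    counts = Counter(values)
    denominator = len(values)
    rows = []
    for cat, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0]))):
        pct = round_half_up(100.0 * cnt / denominator) if denominator else 0
        rows.append((cat, cnt, pct))
    return FrequencyTable(
        dimension=dimension,
        rows=tuple(rows),
        denominator=denominator,
        known_only=known_only,
    )


def tabulate_detentions(
    records: Sequence[RawRecord],
    dimension: str = "role",
) -> FrequencyTable:
    """Frequency table over detention records, full denominator (unknown
    occupations shown as a category rather than dropped)."""
    detained = [r for r in records if r.record_kind == "detention"]
    return tabulate(detained, dimension, known_only=False)


def deadliest_day(
    records: Sequence[RawRecord | LinkedPerson],
) -> tuple[list[dt.date], int]:
    """The date(s) with the most recorded deaths and that count.

    Ties are all returned, sorted chronologically. Records with unknown
    dates cannot contribute; with no dated record at all the question is
    unanswerable and an error is raised.
    """
    dates = [r.event_date for r in records if r.event_date is not None]
    if not dates:
        raise ValueError("no record has a known event_date")
    counts = Counter(dates)
    top = max(counts.values())
    days = sorted(d for d, c in counts.items() if c == top)
    return days, top
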