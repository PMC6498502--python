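"""Casualty-list records: reading, exclusion rules, cross-list linkage,
capture histories and contingency tables.

The unit of input is a named individual as reported by one source list
(:class:`RawRecord`). Records from two or more lists are linked into
:class:`LinkedPerson` entries by exact match on a normalized name, subject
to no conflict among known auxiliary fields (gender, date, place, cause,
and site of gunshot wound for those shot). Linked persons restricted to
three lists aggregate into the seven observable capture-history cells of a
:class:`ContingencyTable`, the input to multiple systems estimation.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import edit_distance_at_most, normalize_name

logger = logging.getLogger(__name__)

__all__ = [
    "RawRecord",
    "LinkedPerson",
    "CaptureHistory",
    "ContingencyTable",
    "ExclusionRules",
    "LinkagePolicy",
    "SchemaError",
    "read_record_list",
    "write_records_csv",
    "apply_exclusions",
    "link_records",
    "persons_to_records",
    "capture_histories",
    "build_contingency_table",
    "write_linked_csv",
    "write_exclusion_log",
]

GENDERS = frozenset({"male", "female", "unknown"})
CAUSES = frozenset(
    {
        "gunshot",
        "explosive_device",
        "torture_in_detention",
        "tear_gas_suffocation",
        "vehicle",
        "other",
        "unknown",
    }
)
GUNSHOT_SITES = frozenset(
    {"head", "chest", "abdomen", "neck", "hip", "leg_thigh", "shoulder", "unspecified"}
)
RECORD_KINDS = frozenset({"death", "injury", "detention"})

#: Column order of the record CSV schema. Blank cells mean "unknown".
CSV_COLUMNS = (
    "source_id",
    "record_kind",
    "name",
    "gender",
    "age_years",
    "minor_flag",
    "event_date",
    "place",
    "cause",
    "gunshot_site",
    "role",
)


class SchemaError(ValueError):
    """A CSV input does not conform to the documented record schema."""


@dataclass(frozen=True)
class RawRecord:
    """One named individual as reported by a single source list."""

    source_id: str
    name: str | None = None
    gender: str = "unknown"
    age_years: int | None = None
    minor_flag: bool | None = None
    event_date: dt.date | None = None
    place: str | None = None
    cause: str = "unknown"
    gunshot_site: str | None = None  # None = not applicable / unknown
    role: str | None = None
    record_kind: str = "death"
    row: int | None = None  # 1-based data-row number in the source CSV

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"invalid gender {self.gender!r}")
        if self.cause not in CAUSES:
            raise ValueError(f"invalid cause {self.cause!r}")
        if self.record_kind not in RECORD_KINDS:
            raise ValueError(f"invalid record_kind {self.record_kind!r}")
        if self.gunshot_site is not None:
            if self.cause != "gunshot":
                raise ValueError("gunshot_site is only applicable when cause is gunshot")
            if self.gunshot_site not in GUNSHOT_SITES:
                raise ValueError(f"invalid gunshot_site {self.gunshot_site!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def normalized_name(self) -> str | None:
        return normalize_name(self.name) if self.name else None


@dataclass(frozen=True)
class LinkedPerson:
    """One individual after cross-list linkage, with canonical fields."""

    person_id: str
    name: str | None
    gender: str
    age_years: int | None
    minor_flag: bool | None
    event_date: dt.date | None
    place: str | None
    cause: str
    gunshot_site: str | None
    role: str | None
    record_kind: str
    member_of: frozenset[str]
    provenance: tuple[RawRecord, ...]

    def __post_init__(self) -> None:
        if not self.member_of:
            raise ValueError("a linked person must appear on at least one list")

    @property
    def normalized_name(self) -> str | None:
        return normalize_name(self.name) if self.name else None


@dataclass(frozen=True)
class CaptureHistory:
    """Per-person list-membership booleans for three named lists."""

    person_id: str
    i: bool
    j: bool
    k: bool

    def __post_init__(self) -> None:
        if not (self.i or self.j or self.k):
            raise ValueError("capture histories exist only for observed persons")


#: Observable capture-history cells in canonical order.
CELL_ORDER = ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1))


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of the seven observable capture-history cells x_ijk.

    The (0,0,0) cell — individuals on no list — is unobserved and is what
    multiple systems estimation predicts.
    """

    x_111: int
    x_110: int
    x_101: int
    x_011: int
    x_100: int
    x_010: int
    x_001: int
    list_labels: tuple[str, str, str] = ("A", "B", "C")
    period: tuple[dt.date, dt.date] | None = None

    def __post_init__(self) -> None:
        for cell in CELL_ORDER:
            if self.cell(cell) < 0:
                raise ValueError(f"cell x_{''.join(map(str, cell))} is negative")
        if len(set(self.list_labels)) != 3:
            raise ValueError("list_labels must be three distinct source ids")

    def cell(self, history: tuple[int, int, int]) -> int:
        return int(getattr(self, "x_" + "".join(str(int(b)) for b in history)))

    def counts(self) -> np.ndarray:
        """Cell counts as a float array in :data:`CELL_ORDER`."""
        return np.array([self.cell(h) for h in CELL_ORDER], dtype=float)

    @property
    def n_obs(self) -> int:
        """Number of individuals on at least one list."""
        return int(self.counts().sum())

    def captured_on(self, label: str) -> int:
        """Number of individuals appearing on the named list."""
        if label not in self.list_labels:
            raise ValueError(f"unknown list label {label!r}; have {self.list_labels}")
        pos = self.list_labels.index(label)
        return int(sum(self.cell(h) for h in CELL_ORDER if h[pos]))

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[int, int, int] | str, int],
        list_labels: tuple[str, str, str] = ("A", "B", "C"),
        period: tuple[dt.date, dt.date] | None = None,
    ) -> "ContingencyTable":
        cells = {}
        for key, value in counts.items():
            if isinstance(key, str):
                key = tuple(int(c) for c in key)
            cells["x_" + "".join(str(int(b)) for b in key)] = int(value)
        for h in CELL_ORDER:
            cells.setdefault("x_" + "".join(map(str, h)), 0)
        return cls(list_labels=list_labels, period=period, **cells)

    def write_csv(self, path: str | Path) -> None:
        """Write the eight-row i,j,k,count table; the 000 row is left blank."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["i", "j", "k", "count"])
            for h in CELL_ORDER:
                writer.writerow([h[0], h[1], h[2], self.cell(h)])
            writer.writerow([0, 0, 0, ""])

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        list_labels: tuple[str, str, str] = ("A", "B", "C"),
    ) -> "ContingencyTable":
        cells: dict[tuple[int, int, int], int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = {"i", "j", "k", "count"} - set(reader.fieldnames or ())
            if missing:
                raise SchemaError(f"contingency CSV missing column(s): {sorted(missing)}")
            for row in reader:
                h = (int(row["i"]), int(row["j"]), int(row["k"]))
                raw = (row["count"] or "").strip()
                if h == (0, 0, 0):
                    continue  # unobserved cell, blank by convention
                if raw in ("", "NA"):
                    raise SchemaError(f"observable cell {h} has no count")
                cells[h] = int(raw)
        missing_cells = [h for h in CELL_ORDER if h not in cells]
        if missing_cells:
            raise SchemaError(f"contingency CSV missing cell row(s): {missing_cells}")
        return cls.from_counts(cells, list_labels=list_labels)


# ---------------------------------------------------------------------------
# Reading and writing record CSVs
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text)


def read_record_list(
    path: str | Path,
    source_id: str | None = None,
    kind: str | None = None,
) -> list[RawRecord]:
    """Read one source list from a CSV file in the documented schema.

    Blank fields map to unknown sentinels. A row whose ``event_date`` does
    not parse as an ISO date is skipped with a logged warning; other
    malformed optional fields degrade to unknown with a warning. ``source_id``
    and ``kind``, when given, override the corresponding columns.
    """
    path = Path(path)
    records: list[RawRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(
                f"{path.name}: missing mandatory column(s): {', '.join(sorted(missing))}"
            )
        for rownum, row in enumerate(reader, start=1):
            get = lambda col: (row.get(col) or "").strip()
            date_text = get("event_date")
            event_date = None
            if date_text:
                try:
                    event_date = _parse_date(date_text)
                except ValueError:
                    logger.warning(
                        "%s row %d: unparseable event_date %r; row skipped",
                        path.name, rownum, date_text,
                    )
                    continue
            age: int | None = None
            if get("age_years"):
                try:
                    age = int(get("age_years"))
                    if age < 0:
                        raise ValueError
                except ValueError:
                    logger.warning(
                        "%s row %d: invalid age_years %r treated as unknown",
                        path.name, rownum, get("age_years"),
                    )
                    age = None
            minor: bool | None = None
            if get("minor_flag"):
                low = get("minor_flag").lower()
                if low in _TRUE:
                    minor = True
                elif low in _FALSE:
                    minor = False
                else:
                    logger.warning(
                        "%s row %d: invalid minor_flag %r treated as unknown",
                        path.name, rownum, get("minor_flag"),
                    )
            gender = get("gender").lower() or "unknown"
            if gender not in GENDERS:
                logger.warning(
                    "%s row %d: invalid gender %r treated as unknown", path.name, rownum, gender
                )
                gender = "unknown"
            cause = get("cause").lower() or "unknown"
            if cause not in CAUSES:
                logger.warning(
                    "%s row %d: invalid cause %r treated as unknown", path.name, rownum, cause
                )
                cause = "unknown"
            site = get("gunshot_site").lower() or None
            if site is not None and (cause != "gunshot" or site not in GUNSHOT_SITES):
                logger.warning(
                    "%s row %d: gunshot_site %r dropped (cause=%s)",
                    path.name, rownum, site, cause,
                )
                site = None
            records.append(
                RawRecord(
                    source_id=source_id or get("source_id"),
                    record_kind=kind or get("record_kind") or "death",
                    name=get("name") or None,
                    gender=gender,
                    age_years=age,
                    minor_flag=minor,
                    event_date=event_date,
                    place=get("place") or None,
                    cause=cause,
                    gunshot_site=site,
                    role=get("role") or None,
                    row=rownum,
                )
            )
    return records


def write_records_csv(records: Iterable[RawRecord], path: str | Path) -> None:
    """Write records in the input CSV schema (round-trips with the reader)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.source_id,
                    r.record_kind,
                    r.name or "",
                    "" if r.gender == "unknown" else r.gender,
                    "" if r.age_years is None else r.age_years,
                    "" if r.minor_flag is None else str(r.minor_flag).lower(),
                    "" if r.event_date is None else r.event_date.isoformat(),
                    r.place or "",
                    "" if r.cause == "unknown" else r.cause,
                    r.gunshot_site or "",
                    r.role or "",
                ]
            )


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionRules:
    """Which records are removed before estimation.

    Deaths of army or security personnel are out of the estimand (civilian
    deaths), and records too thin to link reliably are dropped: a record is
    identifiable if it has a name, or at least two of {date, place, cause}.
    """

    security_role_patterns: tuple[str, ...] = (
        "army",
        "security",
        "police",
        "soldier",
        "military",
        "officer",
    )
    require_identifiable: bool = True


def apply_exclusions(
    records: Sequence[RawRecord],
    rules: ExclusionRules | None = None,
) -> tuple[list[RawRecord], list[tuple[RawRecord, str]]]:
    """Partition *records* into (kept, exclusion log).

    The log pairs each excluded record with the rule that fired. kept plus
    excluded always partition the input.
    """
    rules = rules or ExclusionRules()
    kept: list[RawRecord] = []
    log: list[tuple[RawRecord, str]] = []
    for r in records:
        role = (r.role or "").lower()
        if role and any(pat in role for pat in rules.security_role_patterns):
            log.append((r, "security_personnel"))
            continue
        if rules.require_identifiable and not r.name:
            known = sum(x is not None for x in (r.event_date, r.place)) + (
                r.cause != "unknown"
            )
            if known < 2:
                log.append((r, "insufficient_identification"))
                continue
        kept.append(r)
    return kept, log


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkagePolicy:
    """How records merge across lists.

    Records merge iff their normalized names match (exactly by default;
    ``max_name_edit_distance=1`` enables a conservative fuzzy match) and no
    *known* auxiliary field conflicts. Unknown values never conflict with
    known ones. Merging is transitive: linkage is by connected components.
    """

    agree_fields: tuple[str, ...] = (
        "record_kind",
        "gender",
        "event_date",
        "place",
        "cause",
        "gunshot_site",
    )
    max_name_edit_distance: int = 0


_UNKNOWN_SENTINELS = {None, "unknown"}


def _field_value(r: RawRecord, name: str):
    v = getattr(r, name)
    if v in _UNKNOWN_SENTINELS:
        return None
    if name == "place" and isinstance(v, str):
        return normalize_name(v)
    return v


def _conflicts(a: RawRecord, b: RawRecord, policy: LinkagePolicy) -> bool:
    for f in policy.agree_fields:
        if f == "record_kind":
            if a.record_kind != b.record_kind:
                return True
            continue
        if f == "gunshot_site" and not (a.cause == b.cause == "gunshot"):
            continue
        va, vb = _field_value(a, f), _field_value(b, f)
        if va is not None and vb is not None and va != vb:
            return True
    return False


def _rec_key(r: RawRecord) -> tuple:
    return (
        r.source_id,
        r.row if r.row is not None else 1 << 30,
        r.normalized_name or "",
        str(r.event_date or ""),
        str(r.place or ""),
        r.cause,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _resolve(values: list, unknown) -> object:
    known = [v for v in values if v not in _UNKNOWN_SENTINELS]
    if not known:
        return unknown
    counts = Counter(known)
    best = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return best[0][0]


def link_records(
    records: Iterable[RawRecord],
    policy: LinkagePolicy | None = None,
) -> list[LinkedPerson]:
    """Link records across source lists into persons.

    Deterministic and order-invariant: records are first put into a canonical
    sort, then grouped by normalized name, and within each group connected by
    compatibility (no known-field conflict). Same-source records falling in
    one component are intra-list duplicates: collapsed and logged. Records
    without a usable name never merge with anything.
    """
    policy = policy or LinkagePolicy()
    recs = sorted(records, key=_rec_key)
    n = len(recs)
    uf = _UnionFind(n)

    groups: dict[str, list[int]] = {}
    for idx, r in enumerate(recs):
        key = r.normalized_name
        if key:
            groups.setdefault(key, []).append(idx)

    # Optional fuzzy join of name groups (edit distance on normalized names).
    group_keys = sorted(groups)
    merged_keys: dict[str, list[int]] = {k: list(v) for k, v in groups.items()}
    if policy.max_name_edit_distance > 0:
        for ai in range(len(group_keys)):
            for bi in range(ai + 1, len(group_keys)):
                ka, kb = group_keys[ai], group_keys[bi]
                if edit_distance_at_most(ka, kb, policy.max_name_edit_distance):
                    merged_keys[ka].extend(groups[kb])
                    merged_keys[kb].extend(groups[ka])

    for members in merged_keys.values():
        members = sorted(set(members))
        for a_pos in range(len(members)):
            for b_pos in range(a_pos + 1, len(members)):
                ia, ib = members[a_pos], members[b_pos]
                if not _conflicts(recs[ia], recs[ib], policy):
                    uf.union(ia, ib)

    components: dict[int, list[int]] = {}
    for idx in range(n):
        components.setdefault(uf.find(idx), []).append(idx)

    comps = sorted(
        components.values(),
        key=lambda idxs: _rec_key(recs[idxs[0]]),
    )

    persons: list[LinkedPerson] = []
    for pid, idxs in enumerate(comps):
        group = [recs[i] for i in idxs]
        sources = [r.source_id for r in group]
        dup_sources = [s for s, c in Counter(sources).items() if c > 1]
        if dup_sources:
            logger.info(
                "intra-list duplicate collapsed: %r appears %s times on %s",
                group[0].name,
                Counter(sources),
                sorted(dup_sources),
            )
        cause = _resolve([r.cause for r in group], "unknown")
        persons.append(
            LinkedPerson(
                person_id=f"p{pid + 1:05d}",
                name=_resolve([r.name for r in group], None),
                gender=_resolve([r.gender for r in group], "unknown"),
                age_years=_resolve([r.age_years for r in group], None),
                minor_flag=_resolve([r.minor_flag for r in group], None),
                event_date=_resolve([r.event_date for r in group], None),
                place=_resolve([r.place for r in group], None),
                cause=cause,
                gunshot_site=(
                    _resolve([r.gunshot_site for r in group], None)
                    if cause == "gunshot"
                    else None
                ),
                role=_resolve([r.role for r in group], None),
                record_kind=group[0].record_kind,
                member_of=frozenset(sources),
                provenance=tuple(group),
            )
        )
    return persons


def persons_to_records(persons: Iterable[LinkedPerson]) -> list[RawRecord]:
    """Re-emit one record per (person, source list) with canonical fields.

    Useful for idempotence checks: linking the emitted records reproduces
    the same persons.
    """
    out: list[RawRecord] = []
    for p in persons:
        for src in sorted(p.member_of):
            out.append(
                RawRecord(
                    source_id=src,
                    name=p.name,
                    gender=p.gender,
                    age_years=p.age_years,
                    minor_flag=p.minor_flag,
                    event_date=p.event_date,
                    place=p.place,
                    cause=p.cause,
                    gunshot_site=p.gunshot_site,
                    role=p.role,
                    record_kind=p.record_kind,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Capture histories and contingency tables
# ---------------------------------------------------------------------------

def capture_histories(
    persons: Iterable[LinkedPerson],
    list_labels: tuple[str, str, str],
) -> list[CaptureHistory]:
    """Per-person membership booleans for the three named lists."""
    out = []
    for p in persons:
        out.append(
            CaptureHistory(
                person_id=p.person_id,
                i=list_labels[0] in p.member_of,
                j=list_labels[1] in p.member_of,
                k=list_labels[2] in p.member_of,
            )
        )
    return out


def build_contingency_table(
    persons: Sequence[LinkedPerson],
    list_labels: tuple[str, str, str],
    period: tuple[dt.date, dt.date] | None = None,
) -> ContingencyTable:
    """Aggregate linked persons into the seven observable x_ijk cells.

    *period* is half-open [start, end) on the event date; persons with an
    unknown date are excluded from period-restricted tables and logged
    (silent imputation would bias the cells that drive period splicing).
    """
    if len(set(list_labels)) != 3:
        raise ValueError("exactly three distinct list labels are required")
    cells = {h: 0 for h in CELL_ORDER}
    n_unknown_date = 0
    for p in persons:
        if period is not None:
            if p.event_date is None:
                n_unknown_date += 1
                continue
            if not (period[0] <= p.event_date < period[1]):
                continue
        h = tuple(int(lbl in p.member_of) for lbl in list_labels)
        if h == (0, 0, 0):
            raise ValueError(
                f"person {p.person_id} is on none of {list_labels} "
                f"(member_of={sorted(p.member_of)})"
            )
        cells[h] += 1
    if n_unknown_date:
        logger.warning(
            "%d person(s) with unknown event_date excluded from period-restricted table",
            n_unknown_date,
        )
    return ContingencyTable.from_counts(cells, list_labels=tuple(list_labels), period=period)


def write_linked_csv(persons: Iterable[LinkedPerson], path: str | Path) -> None:
    """One row per linked person; member_of is semicolon-joined."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "person_id",
                "name",
                "gender",
                "age_years",
                "minor_flag",
                "event_date",
                "place",
                "cause",
                "gunshot_site",
                "role",
                "record_kind",
                "member_of",
                "n_records",
            ]
        )
        for p in persons:
            writer.writerow(
                [
                    p.person_id,
                    p.name or "",
                    p.gender,
                    "" if p.age_years is None else p.age_years,
                    "" if p.minor_flag is None else str(p.minor_flag).lower(),
                    "" if p.event_date is None else p.event_date.isoformat(),
                    p.place or "",
                    p.cause,
                    p.gunshot_site or "",
                    p.role or "",
                    p.record_kind,
                    ";".join(sorted(p.member_of)),
                    len(p.provenance),
                ]
            )


def write_exclusion_log(
    log: Iterable[tuple[RawRecord, str]], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "row", "name", "rule"])
        for rec, rule in log:
            writer.writerow([rec.source_id, rec.row or "", rec.name or "", rule])
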