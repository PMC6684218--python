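"""Time-to-detection analysis against literature report dates.

For a drug–ADR pair the forum side contributes the date of its first pair
record and a cumulative post-count curve; the literature side is a table of
publication events at month precision (case report, case series or trial).
Lead time is the whole-month difference between the first literature report
and the first forum report, computed on (year, month) only — positive when
the forum precedes the literature.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .stats import PairRecord

__all__ = [
    "LiteratureEvent",
    "CumulativeSeries",
    "load_literature_events",
    "first_report_date",
    "cumulative_series",
    "lead_time_months",
    "lead_table",
    "write_series",
]

REPORT_TYPES = ("case_report", "case_series", "trial")


@dataclass(frozen=True)
class LiteratureEvent:
    drug_id: str
    group_id: str
    published: date  # day fixed to 1; month precision
    citation: str
    report_type: str

    def __post_init__(self):
        if self.report_type not in REPORT_TYPES:
            raise ValueError(
                f"report_type must be one of {REPORT_TYPES}, got {self.report_type!r}"
            )


@dataclass
class CumulativeSeries:
    """(date, cumulative count) points; dates strictly ascending."""

    points: list[tuple[date, int]]

    def __post_init__(self):
        for (d1, c1), (d2, c2) in zip(self.points, self.points[1:]):
            if not (d1 < d2 and c1 <= c2):
                raise ValueError("series must be date-ascending with non-decreasing counts")

    @property
    def total(self) -> int:
        return self.points[-1][1] if self.points else 0


def load_literature_events(path: str | Path) -> list[LiteratureEvent]:
    """TSV: drug_id, group_id, YYYY-MM, citation, type."""
    events = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"literature line {i}: expected 5 columns, got {len(parts)}")
        try:
            year, month = (int(x) for x in parts[2].split("-")[:2])
            published = date(year, month, 1)
        except ValueError as exc:
            raise ValueError(f"literature line {i}: bad month {parts[2]!r}: {exc}") from None
        events.append(
            LiteratureEvent(
                drug_id=parts[0],
                group_id=parts[1],
                published=published,
                citation=parts[3],
                report_type=parts[4],
            )
        )
    return events


def _matching(records: Sequence[PairRecord], drug_id: str, group_id: str):
    return [r for r in records if r.drug_id == drug_id and r.group_id == group_id]


def first_report_date(
    records: Sequence[PairRecord], drug_id: str, group_id: str
) -> date | None:
    """Earliest pair-record date for the pair, or None without records."""
    dates = [r.date for r in _matching(records, drug_id, group_id)]
    return min(dates) if dates else None


def cumulative_series(
    records: Sequence[PairRecord], drug_id: str, group_id: str
) -> CumulativeSeries:
    """Cumulative post count at each distinct record date."""
    dates = sorted(r.date for r in _matching(records, drug_id, group_id))
    points: list[tuple[date, int]] = []
    for i, d in enumerate(dates, start=1):
        if points and points[-1][0] == d:
            points[-1] = (d, i)
        else:
            points.append((d, i))
    return CumulativeSeries(points=points)


def lead_time_months(first_post: date, literature: date) -> int:
    """Whole months between literature and first forum report ((year, month) only).

    Positive when the forum report precedes the literature report.
    """
    return (literature.year - first_post.year) * 12 + (literature.month - first_post.month)


def lead_table(
    records: Sequence[PairRecord], events: Sequence[LiteratureEvent]
) -> list[dict]:
    """Per literature pair: first forum date, first literature date, lead months.

    When a pair has several literature events the earliest is used.  Pairs
    with no forum records are reported with a None lead.
    """
    first_lit: dict[tuple[str, str], LiteratureEvent] = {}
    for e in events:
        key = (e.drug_id, e.group_id)
        if key not in first_lit or e.published < first_lit[key].published:
            first_lit[key] = e
    rows = []
    for (drug_id, group_id), event in sorted(first_lit.items()):
        first_post = first_report_date(records, drug_id, group_id)
        rows.append(
            {
                "drug_id": drug_id,
                "group_id": group_id,
                "first_post": first_post,
                "first_literature": event.published,
                "citation": event.citation,
                "lead_months": (
                    lead_time_months(first_post, event.published)
                    if first_post is not None
                    else None
                ),
            }
        )
    return rows


def write_series(series: CumulativeSeries, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("date\tcumulative_count\n")
        for d, c in series.points:
            fh.write(f"{d.isoformat()}\t{c}\n")
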