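"""Adherence quantification against the prescribed training dose.

The prescription is approximately 10-15 minutes per day, 5 sessions per
week, for 8 weeks. Engagement logs carry only an anonymous 16-character
tablet code, the session index, a start timestamp, and a duration; weekly
rollups use rolling 7-day windows anchored at the first engagement, since
a home program starts on an arbitrary day.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence, Union

import numpy as np

TABLET_ID_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
TABLET_ID_LENGTH = 16
_TABLET_ID_RE = re.compile(r"^[A-Z0-9]{16}$")


@dataclass(frozen=True)
class EngagementRecord:
    """One training engagement, keyed by the anonymous tablet code."""

    tablet_id: str
    session_index: int
    start: datetime
    duration_s: float
    completed: bool = True

    def __post_init__(self) -> None:
        if not _TABLET_ID_RE.match(self.tablet_id):
            raise ValueError(
                f"tablet_id must be 16 characters from [A-Z0-9], got {self.tablet_id!r}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class Prescription:
    """Prescribed dose: minutes/day range, sessions/week, program weeks."""

    min_minutes_per_day: float = 10.0
    max_minutes_per_day: float = 15.0
    sessions_per_week: int = 5
    weeks: int = 8

    def __post_init__(self) -> None:
        if min(
            self.min_minutes_per_day,
            self.max_minutes_per_day,
            self.sessions_per_week,
            self.weeks,
        ) <= 0:
            raise ValueError("all prescription fields must be positive")

    @property
    def planned_sessions(self) -> int:
        return self.sessions_per_week * self.weeks


@dataclass(frozen=True)
class AdherenceReport:
    """Weekly engagement rollups and the attended/planned fraction."""

    weekly_session_counts: tuple[int, ...]
    weekly_minutes: tuple[float, ...]
    planned_sessions: int
    planned_sessions_per_week: int
    attended_sessions: int
    adherence_fraction: float
    total_minutes: float
    partial_sessions: int
    first_engagement: str | None
    last_engagement: str | None


def new_tablet_id(rng: Union[np.random.Generator, int]) -> str:
    """Draw a random 16-character [A-Z0-9] tablet code.

    Deterministic for a given seed; the 36^16 code space makes collisions
    across any realistic fleet vanishingly unlikely.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(TABLET_ID_ALPHABET), size=TABLET_ID_LENGTH)
    return "".join(TABLET_ID_ALPHABET[i] for i in idx)


def adherence_summary(
    records: Sequence[EngagementRecord], prescription: Prescription = Prescription()
) -> AdherenceReport:
    """Roll engagements into weekly counts and compare with the prescription.

    Weeks are rolling 7-day windows from the first engagement. The
    adherence fraction is attended/planned sessions and is reported as-is
    (it may exceed 1 for over-practising users).
    """
    if not records:
        return AdherenceReport(
            weekly_session_counts=(0,) * prescription.weeks,
            weekly_minutes=(0.0,) * prescription.weeks,
            planned_sessions=prescription.planned_sessions,
            planned_sessions_per_week=prescription.sessions_per_week,
            attended_sessions=0,
            adherence_fraction=0.0,
            total_minutes=0.0,
            partial_sessions=0,
            first_engagement=None,
            last_engagement=None,
        )
    ids = {r.tablet_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix {len(ids)} tablet_ids; expected one")

    ordered = sorted(records, key=lambda r: r.start)
    first = ordered[0].start
    n_weeks = max(
        prescription.weeks,
        (ordered[-1].start - first).days // 7 + 1,
    )
    counts = [0] * n_weeks
    minutes = [0.0] * n_weeks
    partial = 0
    for r in ordered:
        week = (r.start - first).days // 7
        counts[week] += 1
        minutes[week] += r.duration_s / 60.0
        if not r.completed:
            partial += 1
    attended = len(ordered)
    return AdherenceReport(
        weekly_session_counts=tuple(counts),
        weekly_minutes=tuple(minutes),
        planned_sessions=prescription.planned_sessions,
        planned_sessions_per_week=prescription.sessions_per_week,
        attended_sessions=attended,
        adherence_fraction=attended / prescription.planned_sessions,
        total_minutes=sum(minutes),
        partial_sessions=partial,
        first_engagement=ordered[0].start.isoformat(),
        last_engagement=ordered[-1].start.isoformat(),
    )


# ---------------------------------------------------------------------------
# serialization

ENGAGEMENT_HEADER = ["tablet_id", "session_index", "start_iso8601", "duration_s"]


def write_engagement_csv(records: Iterable[EngagementRecord], dest) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w", newline="", encoding="utf-8")
        close = True
    try:
        writer = csv.writer(dest)
        writer.writerow(ENGAGEMENT_HEADER)
        for r in records:
            writer.writerow(
                [r.tablet_id, r.session_index, r.start.isoformat(), repr(r.duration_s)]
            )
    finally:
        if close:
            dest.close()


def read_engagement_csv(source) -> list[EngagementRecord]:
    if isinstance(source, (str, bytes)):
        with open(source, newline="", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    reader = csv.reader(io.StringIO(text))
    header = next(reader, None)
    if header != ENGAGEMENT_HEADER:
        raise ValueError(f"unexpected engagement-log header: {header}")
    out = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            out.append(
                EngagementRecord(
                    tablet_id=row[0],
                    session_index=int(row[1]),
                    start=datetime.fromisoformat(row[2]),
                    duration_s=float(row[3]),
                )
            )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"engagement log line {lineno}: {exc}") from exc
    return out


def report_to_json(report: AdherenceReport) -> str:
    return json.dumps(
        {
            "weekly_session_counts": list(report.weekly_session_counts),
            "weekly_minutes": list(report.weekly_minutes),
            "planned_sessions": report.planned_sessions,
            "planned_sessions_per_week": report.planned_sessions_per_week,
            "attended_sessions": report.attended_sessions,
            "adherence_fraction": report.adherence_fraction,
            "total_minutes": report.total_minutes,
            "partial_sessions": report.partial_sessions,
            "first_engagement": report.first_engagement,
            "last_engagement": report.last_engagement,
        },
        indent=2,
    )


def report_from_json(text: str) -> AdherenceReport:
    raw = json.loads(text)
    return AdherenceReport(
        weekly_session_counts=tuple(int(c) for c in raw["weekly_session_counts"]),
        weekly_minutes=tuple(float(m) for m in raw["weekly_minutes"]),
        planned_sessions=int(raw["planned_sessions"]),
        planned_sessions_per_week=int(raw["planned_sessions_per_week"]),
        attended_sessions=int(raw["attended_sessions"]),
        adherence_fraction=float(raw["adherence_fraction"]),
        total_minutes=float(raw["total_minutes"]),
        partial_sessions=int(raw["partial_sessions"]),
        first_engagement=raw["first_engagement"],
        last_engagement=raw["last_engagement"],
    )


def report_to_text(report: AdherenceReport) -> str:
    lines = [
        f"attended {report.attended_sessions} of {report.planned_sessions} "
        f"planned sessions (adherence {report.adherence_fraction:.2f})",
        f"total training time: {report.total_minutes:.1f} min",
    ]
    for i, (n, mins) in enumerate(
        zip(report.weekly_session_counts, report.weekly_minutes), start=1
    ):
        lines.append(
            f"week {i}: {n}/{report.planned_sessions_per_week} sessions, {mins:.1f} min"
        )
    return "\n".join(lines)
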