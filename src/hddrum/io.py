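"""Comma-separated session output files and tap logs.

Every scored session produces one output file holding four blocks: an
anonymous header (tablet code, session index, start time, duration),
per-event rows for all target beats and extra taps, the eight summary
statistics, and the session-difficulty metadata. Missing values are empty
fields, never sentinel numbers. The schema is versioned and round trips
losslessly.
"""

from __future__ import annotations

import csv
import io as _io
from datetime import datetime
from typing import Optional, Sequence, TextIO, Union

from hddrum.adherence import EngagementRecord
from hddrum.catalog import HandSide
from hddrum.scoring import (
    ExtraTapKind,
    ExtraTapRecord,
    ScoreRecord,
    SessionMetadata,
    SessionResult,
    SessionSummary,
    TapEvent,
)

FORMAT_NAME = "hddrum_output"
FORMAT_VERSION = "1"

EVENT_HEADER = [
    "row_type",
    "target_index",
    "hand",
    "tap_timestamp_ms",
    "accuracy",
    "latency_ms",
    "classification",
]

TAP_LOG_HEADER = ["timestamp_ms", "drum"]

METADATA_FIELDS = ("total_target_beats", "window_duration_ms", "success_threshold_pct")


class OutputParseError(ValueError):
    """Malformed output file; message carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _fmt(value: Optional[float]) -> str:
    return "" if value is None else repr(value)


def write_output(
    result: SessionResult,
    engagement: EngagementRecord,
    dest: Union[str, TextIO],
) -> None:
    """Write a session result and its engagement stamp as one CSV file."""
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w", newline="", encoding="utf-8")
        close = True
    try:
        w = csv.writer(dest)
        w.writerow([FORMAT_NAME, FORMAT_VERSION])
        w.writerow(["tablet_id", engagement.tablet_id])
        w.writerow(["session_index", result.session_index])
        w.writerow(["start", engagement.start.isoformat()])
        w.writerow(["duration_s", repr(engagement.duration_s)])
        w.writerow(["section", "events"])
        w.writerow(EVENT_HEADER)
        for r in result.records:
            w.writerow(
                [
                    "target",
                    r.target_index,
                    r.hand.value,
                    "" if r.matched_tap is None else r.matched_tap.timestamp_ms,
                    r.accuracy,
                    "" if r.latency_ms is None else r.latency_ms,
                    "",
                ]
            )
        for e in result.extras:
            w.writerow(
                [
                    "extra",
                    "",
                    e.tap.drum.value,
                    e.tap.timestamp_ms,
                    e.accuracy,
                    "",
                    e.classification.value,
                ]
            )
        w.writerow(["section", "summary"])
        for name in SessionSummary.FIELDS:
            w.writerow([name, _fmt(getattr(result.summary, name))])
        w.writerow(["section", "metadata"])
        w.writerow(["total_target_beats", result.metadata.total_target_beats])
        w.writerow(["window_duration_ms", repr(result.metadata.window_duration_ms)])
        w.writerow(
            ["success_threshold_pct", repr(result.metadata.success_threshold_pct)]
        )
    finally:
        if close:
            dest.close()


def read_output(source: Union[str, TextIO]) -> tuple[SessionResult, EngagementRecord]:
    """Parse an output file back into its result and engagement record."""
    if isinstance(source, (str, bytes)):
        with open(source, newline="", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    rows = list(csv.reader(_io.StringIO(text)))

    def require(lineno: int, cond: bool, message: str) -> None:
        if not cond:
            raise OutputParseError(lineno, message)

    require(1, bool(rows) and rows[0][:2] == [FORMAT_NAME, FORMAT_VERSION],
            f"expected header '{FORMAT_NAME},{FORMAT_VERSION}'")
    header: dict[str, str] = {}
    i = 1
    while i < len(rows) and rows[i][:1] != ["section"]:
        require(i + 1, len(rows[i]) == 2, "expected key,value pair")
        header[rows[i][0]] = rows[i][1]
        i += 1
    for key in ("tablet_id", "session_index", "start", "duration_s"):
        require(i, key in header, f"missing header field {key!r}")
    require(i + 1, i < len(rows) and rows[i] == ["section", "events"],
            "expected 'section,events'")
    i += 1
    require(i + 1, i < len(rows) and rows[i] == EVENT_HEADER, "bad event header")
    i += 1

    records: list[ScoreRecord] = []
    extras: list[ExtraTapRecord] = []
    while i < len(rows) and rows[i][:1] != ["section"]:
        row = rows[i]
        lineno = i + 1
        require(lineno, len(row) == len(EVENT_HEADER), "wrong event column count")
        try:
            if row[0] == "target":
                hand = HandSide(row[2])
                if row[3] == "":
                    records.append(
                        ScoreRecord(
                            target_index=int(row[1]), hand=hand, accuracy=int(row[4])
                        )
                    )
                else:
                    records.append(
                        ScoreRecord(
                            target_index=int(row[1]),
                            hand=hand,
                            accuracy=int(row[4]),
                            matched_tap=TapEvent(
                                timestamp_ms=int(row[3]), drum=hand
                            ),
                            latency_ms=int(row[5]),
                        )
                    )
            elif row[0] == "extra":
                extras.append(
                    ExtraTapRecord(
                        tap=TapEvent(timestamp_ms=int(row[3]), drum=HandSide(row[2])),
                        classification=ExtraTapKind(row[6]),
                        accuracy=int(row[4]),
                    )
                )
            else:
                raise OutputParseError(lineno, f"unknown row_type {row[0]!r}")
        except OutputParseError:
            raise
        except ValueError as exc:
            raise OutputParseError(lineno, str(exc)) from exc
        i += 1

    require(i + 1, i < len(rows) and rows[i] == ["section", "summary"],
            "expected 'section,summary'")
    i += 1
    summary_raw: dict[str, Optional[float]] = {}
    while i < len(rows) and rows[i][:1] != ["section"]:
        row = rows[i]
        require(i + 1, len(row) == 2, "expected summary key,value pair")
        summary_raw[row[0]] = None if row[1] == "" else float(row[1])
        i += 1
    missing = set(SessionSummary.FIELDS) - set(summary_raw)
    require(i, not missing, f"missing summary fields {sorted(missing)}")
    summary = SessionSummary(**{k: summary_raw[k] for k in SessionSummary.FIELDS})

    require(i + 1, i < len(rows) and rows[i] == ["section", "metadata"],
            "expected 'section,metadata'")
    i += 1
    meta_raw: dict[str, str] = {}
    while i < len(rows):
        if rows[i]:
            require(i + 1, len(rows[i]) == 2, "expected metadata key,value pair")
            meta_raw[rows[i][0]] = rows[i][1]
        i += 1
    missing_meta = set(METADATA_FIELDS) - set(meta_raw)
    require(len(rows), not missing_meta, f"missing metadata fields {sorted(missing_meta)}")

    try:
        engagement = EngagementRecord(
            tablet_id=header["tablet_id"],
            session_index=int(header["session_index"]),
            start=datetime.fromisoformat(header["start"]),
            duration_s=float(header["duration_s"]),
        )
    except ValueError as exc:
        raise OutputParseError(2, str(exc)) from exc
    result = SessionResult(
        session_index=int(header["session_index"]),
        records=tuple(records),
        extras=tuple(extras),
        summary=summary,
        metadata=SessionMetadata(
            total_target_beats=int(meta_raw["total_target_beats"]),
            window_duration_ms=float(meta_raw["window_duration_ms"]),
            success_threshold_pct=float(meta_raw["success_threshold_pct"]),
        ),
    )
    return result, engagement


# ---------------------------------------------------------------------------
# tap logs


def write_taps_csv(taps: Sequence[TapEvent], dest: Union[str, TextIO]) -> None:
    close = False
    if isinstance(dest, (str, bytes)):
        dest = open(dest, "w", newline="", encoding="utf-8")
        close = True
    try:
        w = csv.writer(dest)
        w.writerow(TAP_LOG_HEADER)
        for tap in taps:
            w.writerow([tap.timestamp_ms, tap.drum.value])
    finally:
        if close:
            dest.close()


def read_taps_csv(source: Union[str, TextIO]) -> list[TapEvent]:
    if isinstance(source, (str, bytes)):
        with open(source, newline="", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    reader = csv.reader(_io.StringIO(text))
    header = next(reader, None)
    if header != TAP_LOG_HEADER:
        raise ValueError(f"unexpected tap-log header: {header}")
    taps = []
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        try:
            taps.append(TapEvent(timestamp_ms=int(row[0]), drum=HandSide(row[1])))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"tap log line {lineno}: {exc}") from exc
    return taps
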