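"""Location event logs: ingestion, filtering and day segmentation.

An indoor location system emits one event whenever a resident is read in an
area (a room or courtyard).  This module turns those raw streams into
day-level traces of *visits* — maximal stays in one area with a dwell time —
which are the samples every downstream analysis consumes.  It reads and
writes the MXML process-log interchange format and a flat CSV dialect.

Conventions
-----------
* Timestamps are naive date-times at 1-second resolution; sub-second input
  is truncated.
* A day is the local calendar date (default convention: the timezone of the
  timestamps themselves); a visit never crosses midnight.
* The dwell of the last visit of a day ends at the day's final event — the
  sensor gives no evidence of presence afterwards.  Pass
  ``extend_to_midnight=True`` to :func:`segment_by_day` for the alternative
  convention in which the final stay is carried to 00:00:00.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from lxml import etree

__all__ = [
    "LocationEvent",
    "Visit",
    "Trace",
    "EventLog",
    "LogFormatError",
    "read_mxml",
    "write_mxml",
    "read_csv_events",
    "filter_log",
    "segment_by_day",
]


class LogFormatError(ValueError):
    """Raised when an input file violates the expected log format."""


def _truncate(ts: dt.datetime) -> dt.datetime:
    return ts.replace(microsecond=0)


@dataclass(frozen=True, order=True)
class LocationEvent:
    """One sensor read: a resident identified in an area at a time."""

    resident_id: str
    timestamp: dt.datetime
    area: str

    def __post_init__(self) -> None:
        area = " ".join(self.area.split())
        if not area:
            raise ValueError("area label is empty after whitespace normalization")
        object.__setattr__(self, "area", area)
        object.__setattr__(self, "timestamp", _truncate(self.timestamp))


@dataclass(frozen=True)
class Visit:
    """A maximal stay in one area: start time plus dwell in seconds."""

    area: str
    start: dt.datetime
    dwell: float  # seconds, >= 0

    def __post_init__(self) -> None:
        if self.dwell < 0:
            raise ValueError(f"negative dwell {self.dwell} for area {self.area!r}")

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(seconds=self.dwell)


@dataclass(frozen=True)
class Trace:
    """One resident-day: the ordered visits a resident made on one date."""

    resident_id: str
    day: dt.date
    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "visits", tuple(self.visits))
        for v in self.visits:
            if v.start.date() != self.day:
                raise ValueError(
                    f"visit at {v.start} does not fall on trace day {self.day}"
                )
        for a, b in zip(self.visits, self.visits[1:]):
            if a.area == b.area:
                raise ValueError(f"consecutive visits share area {a.area!r}")
            if a.end > b.start:
                raise ValueError(
                    f"visit ending {a.end} overlaps next visit starting {b.start}"
                )

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(v.area for v in self.visits)


@dataclass
class EventLog:
    """A collection of traces; (resident_id, day) is unique across traces."""

    traces: list[Trace] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(t.resident_id, t.day) for t in self.traces]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (resident, day) traces: {dupes}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def residents(self) -> set[str]:
        return {t.resident_id for t in self.traces}

    @property
    def date_range(self) -> Optional[tuple[dt.date, dt.date]]:
        if not self.traces:
            return None
        days = [t.day for t in self.traces]
        return min(days), max(days)


# ---------------------------------------------------------------------------
# MXML
# ---------------------------------------------------------------------------

#: AuditTrailEntry event types treated as location reads.  Entries with any
#: other type (schedule, assign, ...) are lifecycle bookkeeping, not moves.
ACCEPTED_EVENT_TYPES = frozenset({"complete", "start"})

def _parse_timestamp(text: str) -> dt.datetime:
    text = text.strip()
    # tolerate fractional seconds and trailing zone designators
    ts = pd.Timestamp(text)
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return _truncate(ts.to_pydatetime())


def read_mxml(
    path: str | Path,
    accepted_event_types: frozenset[str] = ACCEPTED_EVENT_TYPES,
) -> EventLog:
    """Read an MXML process log into an :class:`EventLog`.

    Each ``ProcessInstance`` contributes the trace(s) of one resident;
    audit-trail entries are taken in document order, entries whose
    ``EventType`` is neither in *accepted_event_types* nor absent are
    dropped, and the surviving events are day-segmented with
    :func:`segment_by_day` (an instance normally holds a single day).

    Raises
    ------
    LogFormatError
        On malformed XML (naming the line) or a missing ``Timestamp``
        (naming the instance id).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise LogFormatError(
            f"{path}: malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc
    root = tree.getroot()
    events: list[LocationEvent] = []
    n_dropped = 0
    for instance in root.iter("ProcessInstance"):
        inst_id = instance.get("id", "<no id>")
        for entry in instance.iter("AuditTrailEntry"):
            etype_el = entry.find("EventType")
            etype = etype_el.text.strip().lower() if etype_el is not None and etype_el.text else None
            if etype is not None and etype not in accepted_event_types:
                n_dropped += 1
                continue
            area_el = entry.find("WorkflowModelElement")
            if area_el is None or not (area_el.text or "").strip():
                raise LogFormatError(
                    f"{path}: instance {inst_id!r}: entry lacks WorkflowModelElement"
                )
            ts_el = entry.find("Timestamp")
            if ts_el is None or not (ts_el.text or "").strip():
                raise LogFormatError(
                    f"{path}: instance {inst_id!r}: entry lacks Timestamp"
                )
            orig_el = entry.find("Originator")
            if orig_el is not None and (orig_el.text or "").strip():
                resident = orig_el.text.strip()
            else:
                # fall back on the instance id up to the last underscore
                resident = inst_id.rsplit("_", 1)[0]
            events.append(
                LocationEvent(resident, _parse_timestamp(ts_el.text), area_el.text.strip())
            )
    log = segment_by_day(events)
    log.metadata.update(
        {"source": str(path), "format": "mxml", "events_dropped_by_type": n_dropped}
    )
    return log


def write_mxml(log: EventLog, path: str | Path) -> None:
    """Write *log* as a schema-valid MXML file, one ProcessInstance per trace.

    Each visit is emitted as a ``start`` entry at its start time; a visit
    with positive dwell that is the last of its day additionally emits a
    ``complete`` entry at its end, so that ``read_mxml`` recovers every
    dwell exactly.  Visits derived from an event stream are contiguous,
    which makes the round trip the identity.
    """
    root = etree.Element("WorkflowLog")
    etree.SubElement(root, "Source", program="behaviorflow")
    process = etree.SubElement(root, "Process", id="resident-movement")
    for trace in sorted(log.traces, key=lambda t: (t.resident_id, t.day)):
        inst = etree.SubElement(
            process, "ProcessInstance", id=f"{trace.resident_id}_{trace.day.isoformat()}"
        )

        def add_entry(area: str, when: dt.datetime, etype: str) -> None:
            entry = etree.SubElement(inst, "AuditTrailEntry")
            etree.SubElement(entry, "WorkflowModelElement").text = area
            etree.SubElement(entry, "EventType").text = etype
            etree.SubElement(entry, "Timestamp").text = when.isoformat()
            etree.SubElement(entry, "Originator").text = trace.resident_id

        for visit in trace.visits:
            add_entry(visit.area, visit.start, "start")
        if trace.visits:
            last = trace.visits[-1]
            if last.dwell > 0:
                add_entry(last.area, last.end, "complete")
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def read_csv_events(path: str | Path) -> list[LocationEvent]:
    """Read a flat CSV of raw reads (resident_id, timestamp, area).

    Timestamps must be ISO-8601.  Rows are returned sorted by
    (resident_id, timestamp); duplicate rows are kept — repeated sensor
    reads carry dwell information.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"resident_id": str, "area": str})
    required = {"resident_id", "timestamp", "area"}
    missing = required - set(df.columns)
    if missing:
        raise LogFormatError(f"{path}: missing column(s) {sorted(missing)}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0]) + 2  # 1-based, after header
        raise LogFormatError(
            f"{path}: unparseable timestamp {df['timestamp'][row - 2]!r} at row {row}"
        )
    events = [
        LocationEvent(str(r), ts.to_pydatetime(), str(a))
        for r, ts, a in zip(df["resident_id"], parsed, df["area"])
    ]
    events.sort(key=lambda e: (e.resident_id, e.timestamp))
    return events


# ---------------------------------------------------------------------------
# Filtering and segmentation
# ---------------------------------------------------------------------------

def filter_log(
    log: EventLog,
    resident_id: Optional[str] = None,
    date_start: Optional[dt.date] = None,
    date_end: Optional[dt.date] = None,
) -> EventLog:
    """Select the sub-corpus matching a resident and/or a closed date window.

    The input log is not modified; an empty result is valid.
    """
    if date_start is not None and date_end is not None and date_start > date_end:
        raise ValueError(f"date_start {date_start} is after date_end {date_end}")
    kept = [
        t
        for t in log.traces
        if (resident_id is None or t.resident_id == resident_id)
        and (date_start is None or t.day >= date_start)
        and (date_end is None or t.day <= date_end)
    ]
    meta = dict(log.metadata)
    meta["filter"] = {
        "resident_id": resident_id,
        "date_start": date_start.isoformat() if date_start else None,
        "date_end": date_end.isoformat() if date_end else None,
    }
    return EventLog(traces=list(kept), metadata=meta)


def segment_by_day(
    events: Iterable[LocationEvent],
    extend_to_midnight: bool = False,
) -> EventLog:
    """Bucket raw reads into per-(resident, day) traces of visits.

    Within a day, consecutive same-area reads collapse into a single visit
    whose dwell runs from the first read of the area to the next area
    change.  The final visit of a day ends at the day's last read, or at
    the following midnight when *extend_to_midnight* is set; in that mode a
    stay continuing into the next day restarts there at 00:00:00.
    """
    by_resident: dict[str, list[LocationEvent]] = {}
    for ev in events:
        by_resident.setdefault(ev.resident_id, []).append(ev)

    traces: list[Trace] = []
    for resident in sorted(by_resident):
        stream = sorted(by_resident[resident], key=lambda e: e.timestamp)
        by_day: dict[dt.date, list[LocationEvent]] = {}
        for ev in stream:
            by_day.setdefault(ev.timestamp.date(), []).append(ev)
        prev_day: Optional[dt.date] = None
        prev_last_area: Optional[str] = None
        for day in sorted(by_day):
            day_events = by_day[day]
            visits: list[Visit] = []
            day_start = dt.datetime.combine(day, dt.time.min)
            carried = (
                extend_to_midnight
                and prev_day == day - dt.timedelta(days=1)
                and prev_last_area == day_events[0].area
            )
            # collapse runs of the same area
            runs: list[tuple[str, dt.datetime]] = []
            for ev in day_events:
                if not runs or runs[-1][0] != ev.area:
                    runs.append((ev.area, ev.timestamp))
            if carried:
                runs[0] = (runs[0][0], day_start)
            last_ts = day_events[-1].timestamp
            day_end = (
                day_start + dt.timedelta(days=1) if extend_to_midnight else last_ts
            )
            for (area, start), nxt in zip(runs, runs[1:] + [None]):
                end = nxt[1] if nxt is not None else day_end
                visits.append(Visit(area, start, (end - start).total_seconds()))
            traces.append(Trace(resident, day, tuple(visits)))
            prev_day = day
            prev_last_area = runs[-1][0]
    return EventLog(traces=traces)


def expand_to_events(trace: Trace) -> list[LocationEvent]:
    """Inverse of the collapse rule: one event per visit start, plus a
    closing re-read at the end of the final visit when its dwell is positive.
    """
    events = [
        LocationEvent(trace.resident_id, v.start, v.area) for v in trace.visits
    ]
    if trace.visits and trace.visits[-1].dwell > 0:
        last = trace.visits[-1]
        events.append(LocationEvent(trace.resident_id, last.end, last.area))
    return events
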