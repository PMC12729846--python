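"""Clinical event logs: domain types, XES/CSV I/O, and data-preparation rules.

An event log is a collection of *cases* (one patient journey each); a case is
an ordered list of timestamped activity records.  This module covers reading
and writing the IEEE-XES interchange format and flat CSV exports of a hospital
information system reception table, plus the preparation steps applied before
any conformance analysis: label harmonization against a canonical dictionary,
re-spacing of minute-truncated timestamp runs, and recovery of missing case
identifiers by fallback-key matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Sequence

from lxml import etree

__all__ = [
    "Event",
    "Trace",
    "EventLog",
    "ActivityDictionary",
    "ValidationReport",
    "read_xes",
    "write_xes",
    "read_csv",
    "write_csv",
    "harmonize_activities",
    "repair_timestamps",
    "reconcile_case_ids",
    "validate_log",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class Event:
    """One activity execution within a case."""

    case_id: str
    activity: str
    timestamp: datetime
    resource: str | None = None
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.activity:
            raise ValueError(f"event in case {self.case_id!r} has an empty activity label")
        if not isinstance(self.timestamp, datetime):
            raise TypeError(f"event timestamp must be a datetime, got {type(self.timestamp).__name__}")


@dataclass(frozen=True)
class Trace:
    """The time-ordered events of one case."""

    case_id: str
    events: tuple[Event, ...]
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError(f"trace {self.case_id!r} has no events")
        for ev in self.events:
            if ev.case_id != self.case_id:
                raise ValueError(
                    f"trace {self.case_id!r} contains an event of case {ev.case_id!r}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(ev.activity for ev in self.events)

    @property
    def start(self) -> datetime:
        return self.events[0].timestamp

    @property
    def end(self) -> datetime:
        return self.events[-1].timestamp


@dataclass(frozen=True)
class EventLog:
    """A case-grouped event log."""

    traces: tuple[Trace, ...]
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.case_id for t in self.traces]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case ids in log: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.traces)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(ev.activity for t in self.traces for ev in t.events)

    def __iter__(self):
        return iter(self.traces)


@dataclass(frozen=True)
class ActivityDictionary:
    """Raw-to-canonical activity label mapping with a strictness policy.

    ``strict`` fails on any unmapped label; ``lenient`` passes unmapped labels
    through unchanged and reports them.
    """

    mapping: Mapping[str, str]
    policy: str = "strict"

    def __post_init__(self) -> None:
        if self.policy not in ("strict", "lenient"):
            raise ValueError(f"policy must be 'strict' or 'lenient', got {self.policy!r}")


@dataclass(frozen=True)
class ValidationReport:
    n_cases: int
    n_events: int
    issues: tuple[dict, ...]

    @property
    def ok(self) -> bool:
        return len(self.issues) == 0


def _sorted_events(events: Sequence[Event]) -> tuple[Event, ...]:
    # stable sort: equal timestamps keep recorded order
    return tuple(sorted(events, key=lambda ev: ev.timestamp))


def log_from_events(events: Iterable[Event], meta: Mapping[str, str] | None = None) -> EventLog:
    """Group loose events into a log, sorting each case by timestamp (stable)."""
    by_case: dict[str, list[Event]] = {}
    for ev in events:
        by_case.setdefault(ev.case_id, []).append(ev)
    traces = tuple(Trace(cid, _sorted_events(evs)) for cid, evs in by_case.items())
    return EventLog(traces, dict(meta or {}))


# ---------------------------------------------------------------------------
# XES
# ---------------------------------------------------------------------------

_XES_RESERVED = ("concept:name", "time:timestamp", "org:resource", "pm2pim:meta")


def read_xes(path) -> EventLog:
    """Read an IEEE-XES file.

    Uses ``concept:name`` for the activity (and the trace-level case id),
    ``time:timestamp`` for the event time and ``org:resource`` for the
    resource; any other string attribute is kept in ``Event.extras``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XES file {path}: {exc}") from exc
    root = tree.getroot()
    ns = {"x": root.nsmap[None]} if None in root.nsmap else None
    prefix = "x:" if ns else ""

    def attrs_of(el) -> dict[str, str]:
        out = {}
        for child in el:
            tag = etree.QName(child).localname
            if tag in ("string", "date", "int", "float", "boolean"):
                out[child.get("key")] = child.get("value")
        return out

    traces: list[Trace] = []
    log_meta = {k: v for k, v in attrs_of(root).items() if not k.startswith("pm2pim:")}
    for ti, tr_el in enumerate(root.findall(f"{prefix}trace", ns)):
        t_attrs = attrs_of(tr_el)
        case_id = t_attrs.get("concept:name", f"case_{ti}")
        t_meta = {
            k[len("pm2pim:meta:"):]: v
            for k, v in t_attrs.items()
            if k.startswith("pm2pim:meta:")
        }
        events: list[Event] = []
        for ei, ev_el in enumerate(tr_el.findall(f"{prefix}event", ns)):
            e_attrs = attrs_of(ev_el)
            activity = e_attrs.get("concept:name")
            stamp = e_attrs.get("time:timestamp")
            if activity is None:
                raise ValueError(f"case {case_id!r}: event {ei} has no activity (concept:name)")
            if stamp is None:
                raise ValueError(f"case {case_id!r}: event {ei} has no time:timestamp")
            ts = datetime.fromisoformat(stamp)
            if ts.tzinfo is not None:
                ts = ts.replace(tzinfo=None)
            extras = {k: v for k, v in e_attrs.items() if k not in _XES_RESERVED}
            events.append(Event(case_id, activity, ts, e_attrs.get("org:resource"), extras))
        traces.append(Trace(case_id, _sorted_events(events), t_meta))
    return EventLog(tuple(traces), log_meta)


def write_xes(log: EventLog, path) -> None:
    """Write a log as IEEE-XES; round-trips losslessly through :func:`read_xes`."""
    root = etree.Element("log", attrib={"xes.version": "1.0"})
    for k, v in sorted(log.meta.items()):
        etree.SubElement(root, "string", key=str(k), value=str(v))
    for trace in log.traces:
        tr_el = etree.SubElement(root, "trace")
        etree.SubElement(tr_el, "string", key="concept:name", value=trace.case_id)
        for k, v in sorted(trace.meta.items()):
            etree.SubElement(tr_el, "string", key=f"pm2pim:meta:{k}", value=str(v))
        for ev in trace.events:
            ev_el = etree.SubElement(tr_el, "event")
            etree.SubElement(ev_el, "string", key="concept:name", value=ev.activity)
            etree.SubElement(
                ev_el, "date", key="time:timestamp", value=ev.timestamp.strftime(_TS_FORMAT)
            )
            if ev.resource is not None:
                etree.SubElement(ev_el, "string", key="org:resource", value=ev.resource)
            for k, v in sorted(ev.extras.items()):
                etree.SubElement(ev_el, "string", key=str(k), value=str(v))
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "case_id": "ReceptionID",
    "date": "ReceptionDate",
    "time": "ReceptionTime",
    "activity": "ServiceName",
    "resource": "Resource",
}


def read_csv(path, column_map: Mapping[str, str] | None = None) -> EventLog:
    """Read a reception-table style CSV export into an event log.

    ``column_map`` maps the logical fields ``case_id``, ``activity``, ``date``,
    ``time`` (or a single ``timestamp``) and optionally ``resource`` to the
    CSV header names.  Date and time columns are concatenated and parsed as
    ISO-8601; an unparseable row raises an error naming the row number.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        needed = [cmap["case_id"], cmap["activity"]]
        if "timestamp" in cmap:
            needed.append(cmap["timestamp"])
        else:
            needed += [cmap["date"], cmap["time"]]
        for col in needed:
            if col not in header:
                raise KeyError(f"mapped column {col!r} not present in CSV header {header}")
        events: list[Event] = []
        for rownum, row in enumerate(reader, start=2):
            if "timestamp" in cmap:
                stamp = row[cmap["timestamp"]]
            else:
                stamp = f"{row[cmap['date']]}T{row[cmap['time']]}"
            try:
                ts = datetime.fromisoformat(stamp)
            except ValueError as exc:
                raise ValueError(f"row {rownum}: cannot parse timestamp {stamp!r}") from exc
            resource = row.get(cmap.get("resource", ""), None) or None
            used = {cmap["case_id"], cmap["activity"], cmap.get("resource", "")}
            used |= {cmap.get("timestamp", ""), cmap.get("date", ""), cmap.get("time", "")}
            extras = {k: v for k, v in row.items() if k not in used and v}
            events.append(Event(row[cmap["case_id"]], row[cmap["activity"]], ts, resource, extras))
    return log_from_events(events)


def write_csv(log: EventLog, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a log as a flat CSV with separate date and time columns."""
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([cmap["case_id"], cmap["date"], cmap["time"], cmap["activity"], cmap["resource"]])
        for trace in log.traces:
            for ev in trace.events:
                writer.writerow(
                    [
                        ev.case_id,
                        ev.timestamp.strftime("%Y-%m-%d"),
                        ev.timestamp.strftime("%H:%M:%S"),
                        ev.activity,
                        ev.resource or "",
                    ]
                )


# ---------------------------------------------------------------------------
# Preparation rules
# ---------------------------------------------------------------------------


def harmonize_activities(log: EventLog, dictionary: ActivityDictionary) -> EventLog:
    """Replace every activity label by its canonical form.

    Strict policy raises on unmapped labels; lenient passes them through and
    records them under ``meta['unmapped_labels']``.
    """
    unmapped: set[str] = set()
    new_traces = []
    for trace in log.traces:
        new_events = []
        for ev in trace.events:
            if ev.activity in dictionary.mapping:
                new_events.append(replace(ev, activity=dictionary.mapping[ev.activity]))
            else:
                unmapped.add(ev.activity)
                new_events.append(ev)
        new_traces.append(Trace(trace.case_id, tuple(new_events), trace.meta))
    if unmapped and dictionary.policy == "strict":
        raise KeyError(f"unmapped activity labels under strict policy: {sorted(unmapped)}")
    meta = dict(log.meta)
    if unmapped:
        meta["unmapped_labels"] = ",".join(sorted(unmapped))
    return EventLog(tuple(new_traces), meta)


def repair_timestamps(log: EventLog, offset_minutes: float = 5.0) -> EventLog:
    """Re-space runs of events sharing a minute-truncated timestamp.

    Registration systems that record only to the minute produce ties that
    destroy event ordering.  Within each trace, a maximal run of events whose
    timestamps agree once truncated to the minute is re-spaced at successive
    offsets of ``offset_minutes`` (0, +5, +10, ... by default), preserving the
    recorded order.  Already strictly ordered traces come back unchanged; the
    operation is idempotent.
    """
    if offset_minutes <= 0:
        raise ValueError(f"offset_minutes must be positive, got {offset_minutes}")
    step = timedelta(minutes=offset_minutes)
    new_traces = []
    for trace in log.traces:
        evs = list(trace.events)
        out: list[Event] = []
        i = 0
        while i < len(evs):
            j = i
            trunc = evs[i].timestamp.replace(second=0, microsecond=0)
            while j + 1 < len(evs) and evs[j + 1].timestamp.replace(second=0, microsecond=0) == trunc:
                j += 1
            if j == i:
                out.append(evs[i])
            else:
                for k in range(i, j + 1):
                    out.append(replace(evs[k], timestamp=evs[i].timestamp + (k - i) * step))
            i = j + 1
        new_traces.append(Trace(trace.case_id, tuple(out), trace.meta))
    return EventLog(tuple(new_traces), log.meta)


def reconcile_case_ids(
    rows: Sequence[dict],
    fallback_keys: Sequence[str] = ("InsuranceID", "ReceptionDate", "ReceptionTime"),
) -> tuple[list[dict], dict]:
    """Recover missing case ids by unique matching on fallback keys.

    ``rows`` are raw event rows (dicts); a row whose ``case_id`` is empty
    inherits the id of the *unique* id-bearing row agreeing on every fallback
    key.  Ambiguous (two candidate ids) and unmatched rows are dropped and
    counted.  Never invents an id absent from the input.
    """
    def key_of(row):
        return tuple(row.get(k) for k in fallback_keys)

    candidates: dict[tuple, set[str]] = {}
    for row in rows:
        if row.get("case_id"):
            candidates.setdefault(key_of(row), set()).add(row["case_id"])

    kept: list[dict] = []
    report = {"n_input": len(rows), "n_recovered": 0, "n_unresolved": 0, "n_ambiguous": 0}
    for row in rows:
        if row.get("case_id"):
            kept.append(row)
            continue
        ids = candidates.get(key_of(row), set())
        if len(ids) == 1:
            fixed = dict(row)
            fixed["case_id"] = next(iter(ids))
            kept.append(fixed)
            report["n_recovered"] += 1
        elif len(ids) == 0:
            report["n_unresolved"] += 1
        else:
            report["n_ambiguous"] += 1
    return kept, report


def validate_log(log: EventLog) -> ValidationReport:
    """Count cases/events and list ordering violations and empty traces."""
    issues: list[dict] = []
    for trace in log.traces:
        for a, b in zip(trace.events, trace.events[1:]):
            if b.timestamp < a.timestamp:
                issues.append(
                    {
                        "case_id": trace.case_id,
                        "kind": "ordering",
                        "detail": f"{b.activity} at {b.timestamp} before {a.activity} at {a.timestamp}",
                    }
                )
    return ValidationReport(len(log.traces), log.n_events, tuple(issues))
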