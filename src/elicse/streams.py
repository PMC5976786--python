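"""Annotation event streams: parsing, validation, and time discretization.

An annotation event log is a UTF-8 CSV with one row per coded interval and
the columns ``session_id, participant_id, coder_id, group, behavior,
modifier, start_s, stop_s``. Behaviors within one body-part group are
mutually exclusive, so the rows of one (session, participant, coder, group)
form a non-overlapping partition of the observation, made exhaustive by the
group's "none" behavior.

Intervals are half-open ``[start, stop)``: a boundary instant belongs to the
following event, which makes mutual exclusivity decidable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import IntervalError, SchemaError
from .scheme import CodingScheme, Focus

__all__ = [
    "EVENT_COLUMNS",
    "AnnotationEvent",
    "BehaviorStream",
    "StateSequence",
    "ValidationReport",
    "parse_event_log",
    "write_event_log",
    "validate_streams",
    "discretize",
]

EVENT_COLUMNS = (
    "session_id",
    "participant_id",
    "coder_id",
    "group",
    "behavior",
    "modifier",
    "start_s",
    "stop_s",
)


@dataclass(frozen=True)
class AnnotationEvent:
    """One coded interval of one behavior, with its affect modifier."""

    session_id: str
    participant_id: str
    coder_id: str
    group: str
    behavior: str
    modifier: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if not self.stop_s > self.start_s:
            raise IntervalError(
                f"event {self.behavior!r} at [{self.start_s}, {self.stop_s}]: "
                "stop_s must exceed start_s"
            )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class BehaviorStream:
    """Time-ordered events of one body-part group for one participant/coder/session."""

    key: tuple[str, str, str, str]  # (session, participant, coder, group)
    events: list[AnnotationEvent]
    duration_s: float

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start_s, e.stop_s))

    @property
    def session_id(self) -> str:
        return self.key[0]

    @property
    def participant_id(self) -> str:
        return self.key[1]

    @property
    def coder_id(self) -> str:
        return self.key[2]

    @property
    def group(self) -> str:
        return self.key[3]


@dataclass
class StateSequence:
    """A stream discretized to fixed bins; each bin holds a (behavior, modifier) pair."""

    resolution_s: float
    labels: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def behaviors(self) -> list[str]:
        return [b for b, _ in self.labels]


@dataclass
class ValidationReport:
    """Outcome of stream validation; empty ``errors`` iff all invariants hold."""

    errors: list[tuple[tuple, str, tuple[float, float]]] = field(default_factory=list)
    warnings: list[tuple[tuple, str, tuple[float, float]]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, dtype=str, keep_default_na=False)


def parse_event_log(
    source,
    scheme: CodingScheme,
    durations: Mapping[str, float] | None = None,
) -> list[BehaviorStream]:
    """Read an event log (CSV path, file-like, or DataFrame) into streams.

    Every malformed row is collected and reported in a single error — rows
    are never silently dropped. An empty modifier column defaults to
    ``neutral``; behaviors with focus "none" are forced neutral. The session
    duration is the maximum ``stop_s`` seen in the session unless
    ``durations`` supplies it per session.
    """
    df = _as_frame(source)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event log missing columns {missing}")

    problems: list[str] = []
    events: list[AnnotationEvent] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        code = str(getattr(row, "behavior"))
        group = str(getattr(row, "group"))
        if code not in scheme:
            problems.append(f"row {idx}: unknown behavior code {code!r}")
            continue
        if scheme.behavior(code).group != group:
            problems.append(
                f"row {idx}: behavior {code!r} does not belong to group {group!r}"
            )
            continue
        modifier = str(getattr(row, "modifier")).strip() or "neutral"
        if modifier not in scheme.modifiers:
            problems.append(f"row {idx}: unknown modifier {modifier!r}")
            continue
        if scheme.behavior(code).focus == Focus.NONE:
            modifier = "neutral"
        try:
            start = float(getattr(row, "start_s"))
            stop = float(getattr(row, "stop_s"))
        except (TypeError, ValueError):
            problems.append(f"row {idx}: non-numeric start/stop")
            continue
        if start < 0:
            problems.append(f"row {idx}: negative start_s {start}")
            continue
        try:
            events.append(
                AnnotationEvent(
                    session_id=str(getattr(row, "session_id")),
                    participant_id=str(getattr(row, "participant_id")),
                    coder_id=str(getattr(row, "coder_id")),
                    group=group,
                    behavior=code,
                    modifier=modifier,
                    start_s=start,
                    stop_s=stop,
                )
            )
        except IntervalError as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise SchemaError("event log contains invalid rows:\n" + "\n".join(problems))

    session_end: dict[str, float] = {}
    for ev in events:
        session_end[ev.session_id] = max(session_end.get(ev.session_id, 0.0), ev.stop_s)
    if durations:
        session_end.update(durations)

    grouped: dict[tuple, list[AnnotationEvent]] = {}
    for ev in events:
        grouped.setdefault(
            (ev.session_id, ev.participant_id, ev.coder_id, ev.group), []
        ).append(ev)
    return [
        BehaviorStream(key=key, events=evs, duration_s=session_end[key[0]])
        for key, evs in sorted(grouped.items())
    ]


def write_event_log(streams: Iterable[BehaviorStream], path=None) -> pd.DataFrame:
    """Serialize streams back to the event-log table; writes CSV when given a path."""
    rows = [
        {
            "session_id": e.session_id,
            "participant_id": e.participant_id,
            "coder_id": e.coder_id,
            "group": e.group,
            "behavior": e.behavior,
            "modifier": e.modifier,
            "start_s": e.start_s,
            "stop_s": e.stop_s,
        }
        for s in streams
        for e in s.events
    ]
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    if path is not None:
        df.to_csv(path, index=False)
    return df


def validate_streams(
    streams: Iterable[BehaviorStream], gap_tolerance_s: float = 0.04
) -> ValidationReport:
    """Check mutual exclusivity and coverage of every stream.

    Overlaps are always errors. An uncovered gap wider than
    ``gap_tolerance_s`` is an error; a narrower (but positive) gap is a
    warning. No silent auto-filling: coding errors must surface.
    """
    report = ValidationReport()
    for stream in sorted(streams, key=lambda s: s.key):
        evs = stream.events
        cursor = 0.0
        for prev, nxt in zip(evs, evs[1:]):
            if nxt.start_s < prev.stop_s:
                report.errors.append(
                    (stream.key, "overlap", (nxt.start_s, min(prev.stop_s, nxt.stop_s)))
                )
        # coverage sweep over the merged union of intervals
        for ev in evs:
            if ev.start_s > cursor:
                gap = (cursor, ev.start_s)
                if ev.start_s - cursor > gap_tolerance_s:
                    report.errors.append((stream.key, "gap", gap))
                else:
                    report.warnings.append((stream.key, "gap", gap))
            cursor = max(cursor, ev.stop_s)
        if cursor < stream.duration_s:
            gap = (cursor, stream.duration_s)
            if stream.duration_s - cursor > gap_tolerance_s:
                report.errors.append((stream.key, "gap", gap))
            else:
                report.warnings.append((stream.key, "gap", gap))
        if cursor > stream.duration_s + gap_tolerance_s:
            report.errors.append(
                (stream.key, "beyond_duration", (stream.duration_s, cursor))
            )
    return report


def discretize(stream: BehaviorStream, resolution_s: float) -> StateSequence:
    """Sample the stream at bin midpoints into a fixed-resolution state sequence.

    A bin is labeled with the state active at its midpoint under the
    half-open convention: a boundary exactly at a midpoint assigns the bin to
    the later event. Midpoints falling in a (sub-tolerance) gap inherit the
    preceding event's state. Overlapping streams are rejected.
    """
    if resolution_s <= 0:
        raise ValueError("resolution_s must be positive")
    evs = stream.events
    for prev, nxt in zip(evs, evs[1:]):
        if nxt.start_s < prev.stop_s:
            raise IntervalError(
                f"stream {stream.key} has overlapping events at {nxt.start_s}; "
                "validate and fix before discretizing"
            )
    if not evs:
        raise IntervalError(f"stream {stream.key} has no events")
    n_bins = math.ceil(stream.duration_s / resolution_s)
    labels: list[tuple[str, str]] = []
    j = 0
    for i in range(n_bins):
        mid = (i + 0.5) * resolution_s
        while j + 1 < len(evs) and evs[j + 1].start_s <= mid:
            j += 1
        # evs[j] is the last event with start_s <= mid (or the first event)
        ev = evs[j] if evs[j].start_s <= mid or j == 0 else evs[j - 1]
        labels.append((ev.behavior, ev.modifier))
    return StateSequence(resolution_s=resolution_s, labels=labels)
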