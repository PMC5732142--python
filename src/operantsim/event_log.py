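"""Three-level event logging: data model, ASCII log file dialect, table export.

The engine records everything (Record Level 3): every TTL input edge on every
connected channel — whether or not it drives the state flow — every output
event, and every state entry/exit, all on an integer-millisecond grid.
:func:`filter_to_level` derives the reduced views: Level 2 keeps only state
transitions, Level 1 keeps nothing but the header.

File dialect (``.aclog``): ``#``-prefixed ``key: value`` header lines followed
by tab-separated event lines ``time_ms<TAB>kind<TAB>id<TAB>value``.  ``kind``
is ``IN``/``OUT``/``STATE``; ``id`` is a channel index or a state name;
``value`` is ``0``/``1`` for channels and ``enter``/``exit`` for states.
State exits are written explicitly so truncated logs stay parseable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple, TextIO

import pandas as pd

KIND_IN = "IN"
KIND_OUT = "OUT"
KIND_STATE = "STATE"
#: Presentation order of simultaneous events: inputs, then transitions, then outputs.
KIND_ORDER = {KIND_IN: 0, KIND_STATE: 1, KIND_OUT: 2}

FORMAT_VERSION = "aclog/1"


class Event(NamedTuple):
    time_ms: int
    kind: str            # IN | OUT | STATE
    id: int | str        # channel index, or state name for STATE
    value: int | str     # 0|1, or "enter"|"exit" for STATE


@dataclass
class EventLog:
    """Header metadata plus an ordered list of events."""

    header: dict[str, str] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    @property
    def record_level(self) -> int:
        return int(self.header.get("record_level", 3))

    def sort(self) -> None:
        """Stable sort into canonical (time, IN<STATE<OUT) order."""
        self.events.sort(key=lambda e: (e.time_ms, KIND_ORDER[e.kind]))

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]


def filter_to_level(log: EventLog, level: int) -> EventLog:
    """Reduce a Level-3 log to *level*; the header's record_level is updated.

    Level 1 has no data collection; Level 2 keeps only the state stream;
    Level 3 is the identity.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"record level must be 1, 2 or 3, got {level}")
    header = dict(log.header)
    header["record_level"] = str(level)
    if level == 3:
        events = list(log.events)
    elif level == 2:
        events = [e for e in log.events if e.kind == KIND_STATE]
    else:
        events = []
    return EventLog(header=header, events=events)


class LogFormatError(ValueError):
    pass


def _open(dst, mode: str):
    if isinstance(dst, (str, bytes)) or hasattr(dst, "__fspath__"):
        return open(dst, mode, encoding="utf-8", newline="\n"), True
    return dst, False


def write_log(log: EventLog, destination) -> None:
    """Write *log* as ASCII text to a path or text file object."""
    fh, close = _open(destination, "w")
    try:
        fh.write(f"# format: {FORMAT_VERSION}\n")
        for key, value in log.header.items():
            if key == "format":
                continue
            fh.write(f"# {key}: {value}\n")
        for e in log.events:
            fh.write(f"{e.time_ms}\t{e.kind}\t{e.id}\t{e.value}\n")
    finally:
        if close:
            fh.close()


def dumps(log: EventLog) -> str:
    buf = io.StringIO()
    write_log(log, buf)
    return buf.getvalue()


def _parse_event(line: str, lineno: int) -> Event:
    parts = line.split("\t")
    if len(parts) != 4:
        raise LogFormatError(f"line {lineno}: expected 4 tab-separated fields, "
                             f"got {len(parts)}: {line!r}")
    t_s, kind, ident, value = parts
    try:
        t = int(t_s)
    except ValueError:
        raise LogFormatError(f"line {lineno}: bad timestamp {t_s!r}") from None
    if kind == KIND_STATE:
        if value not in ("enter", "exit"):
            raise LogFormatError(f"line {lineno}: STATE value must be "
                                 f"enter/exit, got {value!r}")
        return Event(t, kind, ident, value)
    if kind in (KIND_IN, KIND_OUT):
        try:
            return Event(t, kind, int(ident), int(value))
        except ValueError:
            raise LogFormatError(f"line {lineno}: bad {kind} fields "
                                 f"{ident!r}/{value!r}") from None
    raise LogFormatError(f"line {lineno}: unknown event kind {kind!r}")


def read_log(source) -> EventLog:
    """Parse an ASCII log from a path or text file object."""
    fh, close = _open(source, "r")
    try:
        header: dict[str, str] = {}
        events: list[Event] = []
        version: str | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise LogFormatError(f"line {lineno}: malformed header "
                                         f"line {line!r}")
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "format":
                    version = value
                else:
                    header[key] = value
                continue
            if version is None:
                raise LogFormatError(f"line {lineno}: missing '# format:' header")
            events.append(_parse_event(line, lineno))
        if version is None:
            raise LogFormatError("empty log: missing '# format:' header")
        if version != FORMAT_VERSION:
            raise LogFormatError(f"unsupported log format version {version!r}; "
                                 f"expected {FORMAT_VERSION!r}")
        return EventLog(header=header, events=events)
    finally:
        if close:
            fh.close()


def loads(text: str) -> EventLog:
    return read_log(io.StringIO(text))


_TABLE_COLUMNS = ["time_ms", "kind", "id", "value"]


def to_table(log: EventLog) -> pd.DataFrame:
    """Long-form export: one row per event, lossless columns."""
    df = pd.DataFrame(
        {
            "time_ms": pd.Series([e.time_ms for e in log.events], dtype="int64"),
            "kind": pd.Categorical([e.kind for e in log.events],
                                   categories=[KIND_IN, KIND_STATE, KIND_OUT]),
            "id": pd.Series([str(e.id) for e in log.events], dtype="string"),
            "value": pd.Series([str(e.value) for e in log.events], dtype="string"),
        }
    )
    return df


def from_table(df: pd.DataFrame, header: dict[str, str] | None = None) -> EventLog:
    """Rebuild an :class:`EventLog` from a :func:`to_table` frame."""
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LogFormatError(f"table missing columns: {missing}")
    events = []
    for t, kind, ident, value in zip(df["time_ms"], df["kind"], df["id"], df["value"]):
        if kind == KIND_STATE:
            events.append(Event(int(t), str(kind), str(ident), str(value)))
        else:
            events.append(Event(int(t), str(kind), int(ident), int(value)))
    return EventLog(header=dict(header or {}), events=events)
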