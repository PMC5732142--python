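"""Deterministic virtual-time executor of a session's state machine.

The engine advances an integer millisecond clock and replays a session against
an input source (a prerecorded :class:`InputTrace`, a closed-loop agent, or
both), producing a complete Level-3 :class:`~operantsim.event_log.EventLog`.
Exactly one state is active at every virtual instant; identical
(session, inputs, seed) triples produce byte-identical logs.

Same-instant semantics (shared with the reference tick simulator):

* Within one millisecond, input edges are applied first, then scheduled pulse
  off-edges, then transitions settle, then the newly entered state's actions
  run.  Every applied edge and every state entry receives a global sequence
  number; an edge can trigger a ``when_pin`` rule only in a state entered
  *before* the edge was applied (edge-triggered activation semantics — a
  channel already high at entry does not fire unless the rule is
  ``level_triggered``).
* Transition priority at one instant: ``when_count`` > ``when_var`` >
  ``when_pin`` > ``when_time``; ``when_pin`` ties resolve to the lowest
  channel index, then declaration order.
* ``when_count`` keeps a per-state entry counter (never reset within a run)
  and fires on the entry that reaches its threshold, before the state's
  do-actions execute: the visit is logged with zero duration and no stimuli.
* ``when_time`` durations and ``when_count`` thresholds are evaluated once at
  each state entry; pulse off-edges are scheduled at entry + duration and
  outlive the state unless the action sets ``cancel_on_exit``.
* Random primitives draw from the single generator owned by the run, in
  do/when evaluation order.

:func:`reference_tick_simulator` is a deliberately naive 1-ms-at-a-time
re-implementation of the same contract, kept as an independent code path; the
two must agree event-for-event on any session both can run.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from . import _expr
from .event_log import KIND_IN, KIND_OUT, KIND_STATE, Event, EventLog, filter_to_level
from .task_model import (
    SessionDef,
    StateDef,
    TARGET_NEXT_COMPONENT,
    TARGET_SESSION_EXIT,
    resolve_entry,
)

#: Upper bound on same-instant chained transitions before declaring livelock.
LIVELOCK_LIMIT = 1000

EXIT_SESSION = "session_exit"
EXIT_TIME_CAP = "time_cap"


class EngineRunError(RuntimeError):
    """Runtime failure inside a session run (bad expression, livelock...)."""


class InputEdge(NamedTuple):
    time_ms: int
    channel: int
    level: int  # 0|1


class InputTrace:
    """A time-sorted schedule of input-channel edges.

    Levels must alternate per channel starting from low (the first edge on
    any channel is a rise), and times must be non-negative.
    """

    def __init__(self, edges: Iterable[tuple[int, int, int] | InputEdge] = ()):
        self.edges: list[InputEdge] = [InputEdge(int(t), int(c), int(l))
                                       for t, c, l in edges]
        self.validate()

    def validate(self) -> None:
        last_time = 0
        level: dict[int, int] = {}
        for i, e in enumerate(self.edges):
            if e.time_ms < 0:
                raise ValueError(f"edge {i}: negative time {e.time_ms}")
            if e.time_ms < last_time:
                raise ValueError(f"edge {i}: times not sorted ({e.time_ms} after "
                                 f"{last_time})")
            last_time = e.time_ms
            if e.level not in (0, 1):
                raise ValueError(f"edge {i}: level must be 0 or 1, got {e.level}")
            if level.get(e.channel, 0) == e.level:
                raise ValueError(f"edge {i}: channel {e.channel} levels do not "
                                 f"alternate")
            level[e.channel] = e.level

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, InputTrace) and self.edges == other.edges


def read_trace(source) -> InputTrace:
    """Read a 3-column (time_ms, channel, level) delimited text trace."""
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        source = open(source, "r", encoding="utf-8")
        close = True
    try:
        edges = []
        for lineno, raw in enumerate(source, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 3:
                raise ValueError(f"trace line {lineno}: expected 3 columns, "
                                 f"got {len(parts)}")
            edges.append(tuple(int(p) for p in parts))
        return InputTrace(edges)
    finally:
        if close:
            source.close()


def write_trace(trace: InputTrace, destination) -> None:
    close = False
    if isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__"):
        destination = open(destination, "w", encoding="utf-8", newline="\n")
        close = True
    try:
        destination.write("# time_ms\tchannel\tlevel\n")
        for e in trace.edges:
            destination.write(f"{e.time_ms}\t{e.channel}\t{e.level}\n")
    finally:
        if close:
            destination.close()


@dataclass(frozen=True)
class EngineConfig:
    seed: int = 0
    record_level: Optional[int] = None  # None: use the session's level
    max_virtual_time_ms: int = 10**9
    subject: str = "sim"

    def __post_init__(self):
        if self.max_virtual_time_ms <= 0:
            raise ValueError("max_virtual_time_ms must be positive")


@dataclass
class RunResult:
    log: EventLog
    final_variables: dict[str, int]
    exit_reason: str  # session_exit | time_cap
    final_outputs: dict[int, int] = field(default_factory=dict)
    end_time_ms: int = 0


class EngineView:
    """Read-only window onto a running engine, handed to closed-loop agents."""

    def __init__(self, runner: "SessionRunner"):
        self._runner = runner

    @property
    def variables(self):
        return MappingProxyType(self._runner.variables)

    @property
    def session(self) -> SessionDef:
        return self._runner.session

    @property
    def now_ms(self) -> int:
        return self._runner.t


class _StateRules:
    """Per-state rule split, precomputed once per run."""

    __slots__ = ("count", "var", "pin", "time")

    def __init__(self, state: StateDef):
        self.count = [r for r in state.transitions if r.kind == "when_count"]
        self.var = [r for r in state.transitions if r.kind == "when_var"]
        pins = [(r.channel, i, r) for i, r in enumerate(state.transitions)
                if r.kind == "when_pin"]
        pins.sort(key=lambda p: (p[0], p[1]))  # lowest channel, then declaration
        self.pin = [r for _, _, r in pins]
        times = [r for r in state.transitions if r.kind == "when_time"]
        self.time = times[0] if times else None


class SessionRunner:
    """Event-driven run of one session; use :func:`run_session` normally.

    Exposed so tests can drive execution one virtual instant at a time via
    :meth:`advance_instant` and inspect intermediate engine state.
    """

    def __init__(self, session: SessionDef, config: EngineConfig,
                 trace: InputTrace | None = None, agent=None):
        self.session = session
        self.config = config
        self.agent = agent
        self.rng = np.random.default_rng(config.seed)
        self.variables: dict[str, int] = {
            gv.name: int(gv.initial_value) for gv in session.variables
        }
        self.t = 0
        self._seq = 0
        self.exited = False
        self.exit_reason = EXIT_SESSION
        self.events: list[Event] = []
        self.in_level: dict[int, int] = {}
        self.out_level: dict[int, int] = {}
        # channel -> list of unconsumed rising-edge sequence numbers
        self._pending_edges: dict[int, list[int]] = {}
        # channel -> (off_time, owner_state_name or None if not cancel_on_exit)
        self._pending_offs: dict[int, tuple[int, Optional[str]]] = {}
        self._entry_counts: dict[str, int] = {}
        self._edge_heap: list[tuple[int, int, int, int]] = []
        self._push_counter = 0
        if trace is not None:
            for e in trace:
                self._push_edge(e.time_ms, e.channel, e.level)
        self._rules: dict[str, _StateRules] = {
            s.name: _StateRules(s) for _, s in session.iter_states()
        }
        self._component_of: dict[str, int] = {}
        for ci, comp in enumerate(session.components):
            for s in comp.states:
                self._component_of[s.name] = ci
        self.current: StateDef | None = None
        self._entry_time = 0
        self._entry_seq = 0
        self._deadline: Optional[int] = None
        self._view = EngineView(self)
        self._started = False

    # -- plumbing ---------------------------------------------------------

    def _push_edge(self, time_ms: int, channel: int, level: int) -> None:
        self._push_counter += 1
        heapq.heappush(self._edge_heap,
                       (int(time_ms), self._push_counter, int(channel), int(level)))

    def _log(self, kind: str, ident, value) -> None:
        self.events.append(Event(self.t, kind, ident, value))

    def _eval(self, expression: str, what: str) -> int:
        try:
            return _expr.evaluate(expression, self.variables, self.rng)
        except _expr.ExpressionError as exc:
            state = self.current.name if self.current else "<entry>"
            raise EngineRunError(
                f"state {state!r}, {what} {expression!r}: {exc}") from None

    def _eval_scalar(self, value: int | str, what: str) -> int:
        if isinstance(value, str):
            return self._eval(value, what)
        return int(value)

    # -- output actions ---------------------------------------------------

    def _do_outputs(self, state: StateDef) -> None:
        for act in state.outputs:
            ch = act.channel
            if act.pattern == "set_on":
                if self.out_level.get(ch, 0) == 0:
                    self.out_level[ch] = 1
                    self._log(KIND_OUT, ch, 1)
                self._pending_offs.pop(ch, None)
            elif act.pattern == "set_off":
                if self.out_level.get(ch, 0) == 1:
                    self.out_level[ch] = 0
                    self._log(KIND_OUT, ch, 0)
                self._pending_offs.pop(ch, None)
            else:  # pulse
                dur = self._eval_scalar(act.duration_ms, "pulse duration")
                if dur < 1:
                    raise EngineRunError(
                        f"state {state.name!r}: pulse duration {dur} < 1 ms")
                if self.out_level.get(ch, 0) == 0:
                    self.out_level[ch] = 1
                    self._log(KIND_OUT, ch, 1)
                owner = state.name if act.cancel_on_exit else None
                self._pending_offs[ch] = (self.t + dur, owner)

    def _apply_offs_due(self) -> None:
        for ch in sorted(self._pending_offs):
            off_t, _ = self._pending_offs[ch]
            if off_t == self.t:
                del self._pending_offs[ch]
                self.out_level[ch] = 0
                self._log(KIND_OUT, ch, 0)

    # -- state entry / exit ----------------------------------------------

    def _exit_state(self) -> None:
        assert self.current is not None
        self._log(KIND_STATE, self.current.name, "exit")
        name = self.current.name
        for ch in [c for c, (_, owner) in self._pending_offs.items()
                   if owner == name]:
            del self._pending_offs[ch]
            self.out_level[ch] = 0
            self._log(KIND_OUT, ch, 0)
        self.current = None
        self._deadline = None

    def _finish(self, reason: str) -> None:
        self.exited = True
        self.exit_reason = reason
        self.end_time = self.t

    def _goto(self, target: str) -> None:
        """Resolve *target* and enter it, chaining immediate when_count exits."""
        hops = 0
        while True:
            hops += 1
            if hops > LIVELOCK_LIMIT:
                raise EngineRunError(
                    f"livelock: >{LIVELOCK_LIMIT} chained entries at t={self.t}")
            if target == TARGET_SESSION_EXIT:
                self._finish(EXIT_SESSION)
                return
            if target == TARGET_NEXT_COMPONENT:
                ci = self._component_of[self._last_exited]
                if ci + 1 >= len(self.session.components):
                    self._finish(EXIT_SESSION)
                    return
                state = self.session.components[ci + 1].states[0]
            else:
                state = self.session.find_state(target)

            self._seq += 1
            self._entry_seq = self._seq
            self._entry_time = self.t
            self.t_entry = self.t
            self._log(KIND_STATE, state.name, "enter")
            n = self._entry_counts.get(state.name, 0) + 1
            self._entry_counts[state.name] = n
            fired = None
            for rule in self._rules[state.name].count:
                thr = self._eval_scalar(rule.threshold, "when_count threshold")
                if n >= thr:
                    fired = rule
                    break
            if fired is not None:
                # zero-duration visit: no do-actions execute
                self._log(KIND_STATE, state.name, "exit")
                self._last_exited = state.name
                target = fired.target
                continue

            self.current = state
            # stale edges can never trigger again: entry_seq only grows
            for ch, lst in self._pending_edges.items():
                if lst and lst[0] <= self._entry_seq:
                    self._pending_edges[ch] = [s for s in lst
                                               if s > self._entry_seq]
            for act in state.var_actions:
                self.variables[act.target] = self._eval(act.expression,
                                                        "do-var expression")
            self._do_outputs(state)
            rules = self._rules[state.name]
            if rules.time is not None:
                dur = self._eval_scalar(rules.time.duration_ms,
                                        "when_time duration")
                if dur < 1:
                    raise EngineRunError(
                        f"state {state.name!r}: when_time duration {dur} < 1 ms")
                self._deadline = self.t + dur
            else:
                self._deadline = None
            return

    # -- rule selection ---------------------------------------------------

    def _select_rule(self):
        """First firing rule of the current state at instant ``self.t``."""
        state = self.current
        rules = self._rules[state.name]
        for rule in rules.var:
            if self._eval(rule.condition, "when_var condition") != 0:
                return rule, None
        for rule in rules.pin:
            ch = rule.channel
            if rule.level_triggered:
                if self.in_level.get(ch, 0) == 1:
                    return rule, None
            else:
                pend = self._pending_edges.get(ch)
                if pend and pend[0] > self._entry_seq:
                    return rule, ch
        if rules.time is not None and self._deadline is not None \
                and self.t >= self._deadline:
            return rules.time, None
        return None

    def _settle(self) -> None:
        """Run transitions at the current instant until quiescent."""
        hops = 0
        while not self.exited:
            sel = self._select_rule()
            if sel is None:
                return
            rule, consume_ch = sel
            hops += 1
            if hops > LIVELOCK_LIMIT:
                raise EngineRunError(
                    f"livelock: >{LIVELOCK_LIMIT} transitions at t={self.t} "
                    f"in state {self.current.name!r}")
            if consume_ch is not None:
                self._pending_edges[consume_ch].pop(0)
            self._last_exited = self.current.name
            self._exit_state()
            self._goto(rule.target)

    # -- main loop --------------------------------------------------------

    def start(self) -> None:
        if self._started:
            raise RuntimeError("runner already started")
        self._started = True
        entry = resolve_entry(self.session)
        self._last_exited = entry.name
        n_before = len(self.events)
        self._goto(entry.name)
        self._settle()
        self._notify_agent(n_before)

    def _notify_agent(self, n_before: int) -> None:
        if self.agent is None or self.exited:
            return
        new_events = self.events[n_before:]
        produced = self.agent.respond(self.t, new_events, self._view, self.rng)
        for t_ms, ch, level in produced or ():
            self._push_edge(max(int(t_ms), self.t + 1), ch, level)

    def _next_time(self) -> Optional[int]:
        candidates = []
        if self._edge_heap:
            candidates.append(self._edge_heap[0][0])
        if self._deadline is not None:
            candidates.append(self._deadline)
        if self._pending_offs:
            candidates.append(min(t for t, _ in self._pending_offs.values()))
        return min(candidates) if candidates else None

    def advance_instant(self) -> bool:
        """Process the next eventful virtual instant; False when run is over."""
        if not self._started:
            self.start()
            return not self.exited
        if self.exited:
            return False
        cap = self.config.max_virtual_time_ms
        t_next = self._next_time()
        if t_next is None or t_next > cap:
            self.t = cap
            self._log(KIND_STATE, self.current.name, "exit")
            self._finish(EXIT_TIME_CAP)
            return False
        self.t = t_next
        n_before = len(self.events)
        while self._edge_heap and self._edge_heap[0][0] == self.t:
            _, _, ch, level = heapq.heappop(self._edge_heap)
            if self.in_level.get(ch, 0) == level:
                continue  # merged traces may repeat a level; no-op edges dropped
            self.in_level[ch] = level
            self._seq += 1
            self._log(KIND_IN, ch, level)
            if level == 1:
                self._pending_edges.setdefault(ch, []).append(self._seq)
        self._apply_offs_due()
        self._settle()
        self._notify_agent(n_before)
        return not self.exited

    def run(self) -> RunResult:
        self.start()
        while self.advance_instant():
            pass
        end = self.t if self.exit_reason == EXIT_TIME_CAP else self.end_time
        level = self.config.record_level or self.session.record_level
        log = EventLog(
            header={
                "session": self.session.name,
                "subject": self.config.subject,
                "seed": str(self.config.seed),
                "record_level": str(level),
            },
            events=self.events,
        )
        log.sort()
        log = filter_to_level(log, level)
        return RunResult(
            log=log,
            final_variables=dict(self.variables),
            exit_reason=self.exit_reason,
            final_outputs={ch: lv for ch, lv in sorted(self.out_level.items())},
            end_time_ms=end,
        )


def run_session(session: SessionDef, inputs, config: EngineConfig) -> RunResult:
    """Execute *session* against *inputs* (an :class:`InputTrace`, a
    closed-loop agent exposing ``respond(...)``, or None) and return the
    :class:`RunResult` with a log at the configured record level."""
    trace, agent = None, None
    if inputs is None:
        pass
    elif hasattr(inputs, "respond"):
        agent = inputs
    elif isinstance(inputs, InputTrace):
        trace = inputs
    else:
        trace = InputTrace(inputs)
    return SessionRunner(session, config, trace=trace, agent=agent).run()


# ---------------------------------------------------------------------------
# Reference 1-ms-tick simulator: the semantics-defining oracle.
# ---------------------------------------------------------------------------

def reference_tick_simulator(session: SessionDef, inputs: InputTrace,
                             config: EngineConfig) -> RunResult:
    """Brute-force executor advancing 1 ms per iteration.

    Independent of :class:`SessionRunner`; intended for small sessions and
    short caps.  Only prerecorded traces are supported (no agents).
    """
    if inputs is None:
        inputs = InputTrace()
    if not isinstance(inputs, InputTrace):
        inputs = InputTrace(inputs)
    rng = np.random.default_rng(config.seed)
    variables = {gv.name: int(gv.initial_value) for gv in session.variables}
    events: list[Event] = []
    in_level: dict[int, int] = {}
    out_level: dict[int, int] = {}
    pending_edges: dict[int, list[int]] = {}
    pending_offs: dict[int, tuple[int, Optional[str]]] = {}
    entry_counts: dict[str, int] = {}
    cap = config.max_virtual_time_ms

    edges_by_time: dict[int, list[InputEdge]] = {}
    for e in inputs:
        edges_by_time.setdefault(e.time_ms, []).append(e)

    comp_of = {}
    for ci, comp in enumerate(session.components):
        for s in comp.states:
            comp_of[s.name] = ci

    seq = 0
    state: list = [None]          # current state (boxed for closures)
    entry = {"time": 0, "seq": 0, "deadline": None}
    done = {"exited": False, "reason": EXIT_SESSION, "end": 0}

    def ev(expr_src, what, sname):
        try:
            return _expr.evaluate(expr_src, variables, rng)
        except _expr.ExpressionError as exc:
            raise EngineRunError(f"state {sname!r}, {what} {expr_src!r}: {exc}") \
                from None

    def scalar(value, what, sname):
        return ev(value, what, sname) if isinstance(value, str) else int(value)

    def enter(target: str, t: int, came_from: str):
        nonlocal seq
        hops = 0
        while True:
            hops += 1
            if hops > LIVELOCK_LIMIT:
                raise EngineRunError(f"livelock: >{LIVELOCK_LIMIT} chained "
                                     f"entries at t={t}")
            if target == TARGET_SESSION_EXIT:
                done["exited"], done["end"] = True, t
                return
            if target == TARGET_NEXT_COMPONENT:
                ci = comp_of[came_from]
                if ci + 1 >= len(session.components):
                    done["exited"], done["end"] = True, t
                    return
                st = session.components[ci + 1].states[0]
            else:
                st = session.find_state(target)
            seq += 1
            entry["seq"], entry["time"] = seq, t
            events.append(Event(t, KIND_STATE, st.name, "enter"))
            n = entry_counts.get(st.name, 0) + 1
            entry_counts[st.name] = n
            fired = None
            for rule in st.transitions:
                if rule.kind == "when_count":
                    if n >= scalar(rule.threshold, "when_count threshold", st.name):
                        fired = rule
                        break
            if fired is not None:
                events.append(Event(t, KIND_STATE, st.name, "exit"))
                came_from = st.name
                target = fired.target
                continue
            state[0] = st
            for ch in list(pending_edges):
                pending_edges[ch] = [s for s in pending_edges[ch] if s > seq]
            for act in st.var_actions:
                variables[act.target] = ev(act.expression, "do-var expression",
                                           st.name)
            for act in st.outputs:
                ch = act.channel
                if act.pattern == "set_on":
                    if out_level.get(ch, 0) == 0:
                        out_level[ch] = 1
                        events.append(Event(t, KIND_OUT, ch, 1))
                    pending_offs.pop(ch, None)
                elif act.pattern == "set_off":
                    if out_level.get(ch, 0) == 1:
                        out_level[ch] = 0
                        events.append(Event(t, KIND_OUT, ch, 0))
                    pending_offs.pop(ch, None)
                else:
                    dur = scalar(act.duration_ms, "pulse duration", st.name)
                    if dur < 1:
                        raise EngineRunError(f"state {st.name!r}: pulse "
                                             f"duration {dur} < 1 ms")
                    if out_level.get(ch, 0) == 0:
                        out_level[ch] = 1
                        events.append(Event(t, KIND_OUT, ch, 1))
                    pending_offs[ch] = (t + dur,
                                        st.name if act.cancel_on_exit else None)
            entry["deadline"] = None
            for rule in st.transitions:
                if rule.kind == "when_time":
                    dur = scalar(rule.duration_ms, "when_time duration", st.name)
                    if dur < 1:
                        raise EngineRunError(f"state {st.name!r}: when_time "
                                             f"duration {dur} < 1 ms")
                    entry["deadline"] = t + dur
            return

    def pick_rule(t: int):
        st = state[0]
        for rule in st.transitions:
            if rule.kind == "when_var":
                if ev(rule.condition, "when_var condition", st.name) != 0:
                    return rule, None
        pins = sorted(
            [(r.channel, i, r) for i, r in enumerate(st.transitions)
             if r.kind == "when_pin"],
            key=lambda p: (p[0], p[1]),
        )
        for ch, _, rule in pins:
            if rule.level_triggered:
                if in_level.get(ch, 0) == 1:
                    return rule, None
            else:
                pend = pending_edges.get(ch)
                if pend and pend[0] > entry["seq"]:
                    return rule, ch
        for rule in st.transitions:
            if rule.kind == "when_time" and entry["deadline"] is not None \
                    and t >= entry["deadline"]:
                return rule, None
        return None

    def settle(t: int):
        hops = 0
        while not done["exited"]:
            sel = pick_rule(t)
            if sel is None:
                return
            rule, consume_ch = sel
            hops += 1
            if hops > LIVELOCK_LIMIT:
                raise EngineRunError(f"livelock: >{LIVELOCK_LIMIT} transitions "
                                     f"at t={t} in state {state[0].name!r}")
            if consume_ch is not None:
                pending_edges[consume_ch].pop(0)
            events.append(Event(t, KIND_STATE, state[0].name, "exit"))
            came_from = state[0].name
            for ch in [c for c, (_, owner) in pending_offs.items()
                       if owner == came_from]:
                del pending_offs[ch]
                out_level[ch] = 0
                events.append(Event(t, KIND_OUT, ch, 0))
            state[0] = None
            entry["deadline"] = None
            enter(rule.target, t, came_from)

    first = resolve_entry(session)
    enter(first.name, 0, first.name)
    settle(0)
    t = 0
    if not done["exited"]:
        for t in range(0, cap + 1):
            for e in edges_by_time.get(t, ()):
                if in_level.get(e.channel, 0) == e.level:
                    continue
                in_level[e.channel] = e.level
                seq += 1
                events.append(Event(t, KIND_IN, e.channel, e.level))
                if e.level == 1:
                    pending_edges.setdefault(e.channel, []).append(seq)
            for ch in sorted(pending_offs):
                off_t, _ = pending_offs[ch]
                if off_t == t:
                    del pending_offs[ch]
                    out_level[ch] = 0
                    events.append(Event(t, KIND_OUT, ch, 0))
            settle(t)
            if done["exited"]:
                break
        else:
            events.append(Event(cap, KIND_STATE, state[0].name, "exit"))
            done["reason"], done["end"] = EXIT_TIME_CAP, cap

    level = config.record_level or session.record_level
    log = EventLog(
        header={
            "session": session.name,
            "subject": config.subject,
            "seed": str(config.seed),
            "record_level": str(level),
        },
        events=events,
    )
    log.sort()
    log = filter_to_level(log, level)
    return RunResult(
        log=log,
        final_variables=dict(variables),
        exit_reason=done["reason"],
        final_outputs={ch: lv for ch, lv in sorted(out_level.items())},
        end_time_ms=done["end"],
    )
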