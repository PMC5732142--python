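"""Domain types for the State Notation task hierarchy plus a static validator.

A behavioral session is a finite state machine: each :class:`StateDef` bundles
output actions (the *do*-functions: drive TTL output lines, update global
variables) with transition rules (the *when*-functions: entry-count, input-pin,
time-out and variable conditions).  States are grouped into ordered
:class:`ComponentDef` collections which form a :class:`SessionDef`; execution
always starts at the first state of the first component and exactly one state
is active at any virtual instant.

The :class:`HardwareProfile` captures the limits of the microcontroller the
formalism emulates: 6 TTL input lines, 8 TTL output lines, and (for the
low-end board profile, ``UNO``) a memory budget of at most 20 states per
session.  Profile enforcement is a property of the profile, not of the engine:
the ``UNLIMITED`` profile disables the state-count cap for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

from . import _expr

TARGET_NEXT_COMPONENT = "next_component"
TARGET_SESSION_EXIT = "session_exit"
SPECIAL_TARGETS = (TARGET_NEXT_COMPONENT, TARGET_SESSION_EXIT)

PATTERNS = ("set_on", "set_off", "pulse")
RULE_KINDS = ("when_count", "when_pin", "when_time", "when_var")


def _is_identifier(name: str) -> bool:
    return bool(name) and not any(ch.isspace() for ch in name)


@dataclass(frozen=True)
class HardwareProfile:
    """Channel counts and the session-size budget of a target board."""

    name: str
    n_inputs: int = 6
    n_outputs: int = 8
    max_states: Optional[int] = 20  # None disables enforcement


#: Low-end board profile: the 20-state memory budget is enforced.
UNO = HardwareProfile("uno")
#: Testing profile: same channel counts, no state-count cap.
UNLIMITED = HardwareProfile("unlimited", max_states=None)

_NAMED_PROFILES = {"uno": UNO, "unlimited": UNLIMITED}


def profile_by_name(name: str) -> HardwareProfile:
    try:
        return _NAMED_PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown hardware profile {name!r}; "
                       f"known: {sorted(_NAMED_PROFILES)}") from None


@dataclass(frozen=True)
class GlobalVariable:
    name: str
    initial_value: int = 0


@dataclass(frozen=True)
class OutputAction:
    """Drive one TTL output line: latch on/off, or pulse for ``duration_ms``.

    ``duration_ms`` (pulse only) may be an integer or the name of a global
    variable / expression resolved at state entry.  A pulse outlives its state
    by default — the off edge is scheduled at entry + duration regardless of
    transitions — unless ``cancel_on_exit`` is set.
    """

    channel: int
    pattern: str  # set_on | set_off | pulse
    duration_ms: int | str | None = None
    cancel_on_exit: bool = False


@dataclass(frozen=True)
class VarAction:
    """Assign ``target = expression`` at state entry (a *do-var*)."""

    target: str
    expression: str


@dataclass(frozen=True)
class TransitionRule:
    """One *when*-function: condition kind, its parameter, and a destination.

    ``target`` is a state name, ``"next_component"`` (first state of the
    following component; from the last component this means session exit) or
    ``"session_exit"``.
    """

    kind: str
    target: str
    threshold: int | str | None = None      # when_count
    channel: int | None = None              # when_pin
    duration_ms: int | str | None = None    # when_time
    condition: str | None = None            # when_var
    level_triggered: bool = False           # when_pin: fire on level, not edge


def when_count(threshold: int | str, target: str) -> TransitionRule:
    return TransitionRule("when_count", target, threshold=threshold)


def when_pin(channel: int, target: str, *, level_triggered: bool = False) -> TransitionRule:
    return TransitionRule("when_pin", target, channel=channel,
                          level_triggered=level_triggered)


def when_time(duration_ms: int | str, target: str) -> TransitionRule:
    return TransitionRule("when_time", target, duration_ms=duration_ms)


def when_var(condition: str, target: str) -> TransitionRule:
    return TransitionRule("when_var", target, condition=condition)


@dataclass(frozen=True)
class StateDef:
    name: str
    outputs: tuple[OutputAction, ...] = ()
    var_actions: tuple[VarAction, ...] = ()
    transitions: tuple[TransitionRule, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "outputs", tuple(self.outputs))
        object.__setattr__(self, "var_actions", tuple(self.var_actions))
        object.__setattr__(self, "transitions", tuple(self.transitions))


@dataclass(frozen=True)
class ComponentDef:
    name: str
    states: tuple[StateDef, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))


@dataclass(frozen=True)
class SessionDef:
    name: str
    profile: HardwareProfile = UNO
    variables: tuple[GlobalVariable, ...] = ()
    components: tuple[ComponentDef, ...] = ()
    record_level: int = 3

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "components", tuple(self.components))

    def iter_states(self) -> Iterator[tuple[ComponentDef, StateDef]]:
        for comp in self.components:
            for state in comp.states:
                yield comp, state

    def state_names(self) -> list[str]:
        return [s.name for _, s in self.iter_states()]

    def find_state(self, name: str) -> StateDef:
        for _, s in self.iter_states():
            if s.name == name:
                return s
        raise KeyError(name)

    def with_record_level(self, level: int) -> "SessionDef":
        return replace(self, record_level=level)


@dataclass(frozen=True)
class Violation:
    """One validator finding; violations are data, never exceptions."""

    rule_id: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.rule_id}] {self.location}: {self.message}"


def _check_expr(expr: str, declared: set[str], rule_id: str, loc: str,
                out: list[Violation]) -> None:
    try:
        unknown = _expr.variables(expr) - declared
    except _expr.ExpressionError as exc:
        out.append(Violation("expression_syntax", loc, str(exc)))
        return
    for name in sorted(unknown):
        out.append(Violation(rule_id, loc, f"undeclared variable {name!r} in {expr!r}"))


def validate_session(session: SessionDef) -> list[Violation]:
    """Statically check *session*; an empty list means it is runnable.

    Checks: profile sanity, identifier rules, unique variable/state names,
    channel ranges against the profile, pulse/duration consistency, at most
    one time-out rule per state, resolvable transition targets, expression
    well-formedness over declared variables, the record level, and — when the
    profile enforces it — the total state-count budget.

    Validation is pure and idempotent: repeated calls return equal lists.
    """
    v: list[Violation] = []
    prof = session.profile
    for fld, val in (("n_inputs", prof.n_inputs), ("n_outputs", prof.n_outputs)):
        if val < 1:
            v.append(Violation("profile_counts", f"profile.{fld}",
                               f"{fld} must be >= 1, got {val}"))
    if prof.max_states is not None and prof.max_states < 1:
        v.append(Violation("profile_counts", "profile.max_states",
                           f"max_states must be >= 1 or None, got {prof.max_states}"))

    declared: set[str] = set()
    for gv in session.variables:
        loc = f"variables.{gv.name}"
        if not _is_identifier(gv.name):
            v.append(Violation("variable_identifier", loc,
                               f"variable name {gv.name!r} is not a valid identifier"))
        if gv.name in declared:
            v.append(Violation("duplicate_variable", loc,
                               f"variable {gv.name!r} declared more than once"))
        if gv.name in _expr.RANDOM_PRIMITIVES:
            v.append(Violation("variable_identifier", loc,
                               f"variable name {gv.name!r} shadows a random primitive"))
        declared.add(gv.name)

    if not session.components:
        v.append(Violation("empty_session", "components",
                           "session has no components"))
    names: set[str] = set()
    all_names = set(session.state_names())
    n_states = 0
    for comp in session.components:
        if not comp.states:
            v.append(Violation("empty_component", f"components.{comp.name}",
                               f"component {comp.name!r} has no states"))
        for state in comp.states:
            n_states += 1
            loc = f"{comp.name}.{state.name}"
            if not _is_identifier(state.name):
                v.append(Violation("state_identifier", loc,
                                   f"state name {state.name!r} is not a valid identifier"))
            if state.name in names:
                v.append(Violation("duplicate_state", loc,
                                   f"state name {state.name!r} is not unique"))
            names.add(state.name)

            for i, act in enumerate(state.outputs):
                aloc = f"{loc}.outputs[{i}]"
                if act.pattern not in PATTERNS:
                    v.append(Violation("output_pattern", aloc,
                                       f"unknown pattern {act.pattern!r}"))
                if not 1 <= act.channel <= prof.n_outputs:
                    v.append(Violation("channel_range", aloc,
                                       f"output channel {act.channel} outside "
                                       f"1..{prof.n_outputs}"))
                if (act.pattern == "pulse") != (act.duration_ms is not None):
                    v.append(Violation("duration_required", aloc,
                                       "duration_ms present iff pattern is 'pulse'"))
                if isinstance(act.duration_ms, str):
                    _check_expr(act.duration_ms, declared, "undeclared_variable",
                                aloc, v)
                elif act.duration_ms is not None and act.duration_ms < 1:
                    v.append(Violation("duration_positive", aloc,
                                       f"duration_ms must be >= 1, got {act.duration_ms}"))

            for i, act in enumerate(state.var_actions):
                aloc = f"{loc}.var_actions[{i}]"
                if act.target not in declared:
                    v.append(Violation("undeclared_variable", aloc,
                                       f"assignment to undeclared variable "
                                       f"{act.target!r}"))
                _check_expr(act.expression, declared, "undeclared_variable", aloc, v)

            n_time = 0
            for i, rule in enumerate(state.transitions):
                rloc = f"{loc}.transitions[{i}]"
                if rule.kind not in RULE_KINDS:
                    v.append(Violation("rule_kind", rloc,
                                       f"unknown rule kind {rule.kind!r}"))
                    continue
                if rule.kind == "when_time":
                    n_time += 1
                    if isinstance(rule.duration_ms, str):
                        _check_expr(rule.duration_ms, declared,
                                    "undeclared_variable", rloc, v)
                    elif rule.duration_ms is None or rule.duration_ms < 1:
                        v.append(Violation("duration_positive", rloc,
                                           f"when_time duration must be >= 1, "
                                           f"got {rule.duration_ms}"))
                elif rule.kind == "when_pin":
                    if rule.channel is None or not 1 <= rule.channel <= prof.n_inputs:
                        v.append(Violation("channel_range", rloc,
                                           f"input channel {rule.channel} outside "
                                           f"1..{prof.n_inputs}"))
                elif rule.kind == "when_count":
                    if isinstance(rule.threshold, str):
                        _check_expr(rule.threshold, declared,
                                    "undeclared_variable", rloc, v)
                    elif rule.threshold is None or rule.threshold < 1:
                        v.append(Violation("threshold_positive", rloc,
                                           f"when_count threshold must be >= 1, "
                                           f"got {rule.threshold}"))
                else:  # when_var
                    if rule.condition is None:
                        v.append(Violation("condition_required", rloc,
                                           "when_var rule needs a condition"))
                    else:
                        _check_expr(rule.condition, declared,
                                    "undeclared_variable", rloc, v)
                        try:
                            if _expr.uses_random(rule.condition):
                                # conditions are re-evaluated; randomness there
                                # would make fire times draw-order dependent
                                v.append(Violation(
                                    "random_in_condition", rloc,
                                    "when_var conditions must be deterministic "
                                    "(no random primitives)"))
                        except _expr.ExpressionError:
                            pass  # already reported as expression_syntax
                if (rule.target not in SPECIAL_TARGETS
                        and rule.target not in all_names):
                    v.append(Violation("unresolved_target", rloc,
                                       f"transition target {rule.target!r} is not "
                                       f"a state name"))
            if n_time > 1:
                v.append(Violation("multiple_when_time", loc,
                                   f"state has {n_time} when_time rules; at most 1"))

    if prof.max_states is not None and n_states > prof.max_states:
        v.append(Violation("max_states", "session",
                           f"session has {n_states} states; profile "
                           f"{prof.name!r} allows max_states={prof.max_states}"))
    if session.record_level not in (1, 2, 3):
        v.append(Violation("record_level", "session",
                           f"record_level must be 1, 2 or 3, "
                           f"got {session.record_level}"))
    return v


def resolve_entry(session: SessionDef) -> StateDef:
    """The engine's start state: first state of the first component."""
    if not session.components or not session.components[0].states:
        raise ValueError("session has no entry state (empty component list)")
    return session.components[0].states[0]
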