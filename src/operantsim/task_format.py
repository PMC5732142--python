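"""Human-editable structured-text (YAML dialect) serialization of sessions.

One canonical document layout with top-level keys ``session``, ``profile``,
``record_level``, ``variables`` and ``components``.  Durations keep an
explicit ``_ms`` suffix in key names so units cannot drift.  ``dump_session``
emits a canonical form (fixed key order via sorted keys, components and states
in declaration order, defaults omitted) so two dumps of equal sessions are
byte-identical, and ``dump ∘ load`` is idempotent after one pass.
"""

from __future__ import annotations

import yaml

from .task_model import (
    ComponentDef,
    GlobalVariable,
    HardwareProfile,
    OutputAction,
    SessionDef,
    StateDef,
    TransitionRule,
    VarAction,
    profile_by_name,
)

TASK_FILE_SUFFIX = ".task.yaml"

_RULE_KIND_SHORT = {"when_count": "count", "when_pin": "pin",
                    "when_time": "time", "when_var": "var"}
_RULE_KIND_LONG = {v: k for k, v in _RULE_KIND_SHORT.items()}


class TaskFormatError(ValueError):
    """Malformed or unrecognized task document."""


def _require_keys(mapping: dict, allowed: set[str], required: set[str],
                  where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise TaskFormatError(f"{where}: unknown key(s) {sorted(unknown)}; "
                              f"allowed: {sorted(allowed)}")
    missing = required - set(mapping)
    if missing:
        raise TaskFormatError(f"{where}: missing required key(s) "
                              f"{sorted(missing)}")


def _load_profile(node) -> HardwareProfile:
    if isinstance(node, str):
        try:
            return profile_by_name(node)
        except KeyError as exc:
            raise TaskFormatError(str(exc)) from None
    if not isinstance(node, dict):
        raise TaskFormatError("profile: expected a name or a mapping")
    _require_keys(node, {"name", "n_inputs", "n_outputs", "max_states"},
                  {"name"}, "profile")
    return HardwareProfile(
        name=str(node["name"]),
        n_inputs=int(node.get("n_inputs", 6)),
        n_outputs=int(node.get("n_outputs", 8)),
        max_states=(None if node.get("max_states", 20) is None
                    else int(node.get("max_states", 20))),
    )


def _load_output(node: dict, where: str) -> OutputAction:
    _require_keys(node, {"channel", "pattern", "duration_ms", "cancel_on_exit"},
                  {"channel", "pattern"}, where)
    dur = node.get("duration_ms")
    if isinstance(dur, (int, str)) or dur is None:
        pass
    else:
        raise TaskFormatError(f"{where}: duration_ms must be an integer or a "
                              f"variable reference")
    return OutputAction(
        channel=int(node["channel"]),
        pattern=str(node["pattern"]),
        duration_ms=dur,
        cancel_on_exit=bool(node.get("cancel_on_exit", False)),
    )


def _load_rule(node: dict, where: str) -> TransitionRule:
    _require_keys(node, {"kind", "target", "threshold", "channel",
                         "duration_ms", "cond", "level_triggered"},
                  {"kind", "target"}, where)
    kind = str(node["kind"])
    if kind not in _RULE_KIND_LONG:
        raise TaskFormatError(f"{where}: unknown rule kind {kind!r}; expected "
                              f"one of {sorted(_RULE_KIND_LONG)}")
    return TransitionRule(
        kind=_RULE_KIND_LONG[kind],
        target=str(node["target"]),
        threshold=node.get("threshold"),
        channel=(None if node.get("channel") is None else int(node["channel"])),
        duration_ms=node.get("duration_ms"),
        condition=(None if node.get("cond") is None else str(node["cond"])),
        level_triggered=bool(node.get("level_triggered", False)),
    )


def _load_state(node: dict, where: str) -> StateDef:
    _require_keys(node, {"name", "outputs", "vars", "when"}, {"name"}, where)
    name = str(node["name"])
    outputs = tuple(
        _load_output(o, f"{where}.outputs[{i}]")
        for i, o in enumerate(node.get("outputs") or ())
    )
    var_actions = []
    for i, v in enumerate(node.get("vars") or ()):
        _require_keys(v, {"target", "expr"}, {"target", "expr"},
                      f"{where}.vars[{i}]")
        var_actions.append(VarAction(target=str(v["target"]),
                                     expression=str(v["expr"])))
    rules = tuple(
        _load_rule(r, f"{where}.when[{i}]")
        for i, r in enumerate(node.get("when") or ())
    )
    return StateDef(name=name, outputs=outputs,
                    var_actions=tuple(var_actions), transitions=rules)


def load_session(document: str) -> SessionDef:
    """Parse a task document (YAML text) into a :class:`SessionDef`.

    Structural errors (unknown keys, duplicate state names, bad shapes) raise
    :class:`TaskFormatError`; semantic problems are left to
    :func:`~operantsim.task_model.validate_session`.
    """
    try:
        data = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise TaskFormatError(f"not a well-formed task document: {exc}") from None
    if not isinstance(data, dict):
        raise TaskFormatError("task document must be a mapping at top level")
    _require_keys(data, {"session", "profile", "record_level", "variables",
                         "components"}, {"session", "components"}, "document")
    profile = _load_profile(data.get("profile", "uno"))
    record_level = int(data.get("record_level", 3))  # Level 3: comprehensive DAQ

    variables = []
    for i, v in enumerate(data.get("variables") or ()):
        _require_keys(v, {"name", "init"}, {"name"}, f"variables[{i}]")
        variables.append(GlobalVariable(name=str(v["name"]),
                                        initial_value=int(v.get("init", 0))))

    components = []
    seen_states: set[str] = set()
    for ci, c in enumerate(data.get("components") or ()):
        _require_keys(c, {"name", "states"}, {"name", "states"},
                      f"components[{ci}]")
        states = []
        for si, s in enumerate(c.get("states") or ()):
            state = _load_state(s, f"components[{ci}].states[{si}]")
            if state.name in seen_states:
                raise TaskFormatError(f"duplicate state name {state.name!r}")
            seen_states.add(state.name)
            states.append(state)
        components.append(ComponentDef(name=str(c["name"]),
                                       states=tuple(states)))

    return SessionDef(
        name=str(data["session"]),
        profile=profile,
        variables=tuple(variables),
        components=tuple(components),
        record_level=record_level,
    )


def _dump_output(act: OutputAction) -> dict:
    node: dict = {"channel": act.channel, "pattern": act.pattern}
    if act.duration_ms is not None:
        node["duration_ms"] = act.duration_ms
    if act.cancel_on_exit:
        node["cancel_on_exit"] = True
    return node


def _dump_rule(rule: TransitionRule) -> dict:
    node: dict = {"kind": _RULE_KIND_SHORT[rule.kind], "target": rule.target}
    if rule.kind == "when_count":
        node["threshold"] = rule.threshold
    elif rule.kind == "when_pin":
        node["channel"] = rule.channel
        if rule.level_triggered:
            node["level_triggered"] = True
    elif rule.kind == "when_time":
        node["duration_ms"] = rule.duration_ms
    else:
        node["cond"] = rule.condition
    return node


def dump_session(session: SessionDef) -> str:
    """Serialize to the canonical document text (byte-stable per session)."""
    data: dict = {
        "session": session.name,
        "profile": {
            "name": session.profile.name,
            "n_inputs": session.profile.n_inputs,
            "n_outputs": session.profile.n_outputs,
            "max_states": session.profile.max_states,
        },
        "record_level": session.record_level,
        "variables": [{"name": v.name, "init": v.initial_value}
                      for v in session.variables],
        "components": [
            {
                "name": comp.name,
                "states": [
                    {
                        "name": s.name,
                        **({"outputs": [_dump_output(a) for a in s.outputs]}
                           if s.outputs else {}),
                        **({"vars": [{"target": a.target, "expr": a.expression}
                                     for a in s.var_actions]}
                           if s.var_actions else {}),
                        **({"when": [_dump_rule(r) for r in s.transitions]}
                           if s.transitions else {}),
                    }
                    for s in comp.states
                ],
            }
            for comp in session.components
        ],
    }
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False,
                          width=100)


def read_task_file(path) -> SessionDef:
    with open(path, "r", encoding="utf-8") as fh:
        return load_session(fh.read())


def write_task_file(session: SessionDef, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(dump_session(session))
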