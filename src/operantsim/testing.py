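"""Randomized session and trace generators for fuzz/property testing.

:func:`random_session` emits small sessions that always pass the validator;
together with :func:`random_trace` they drive the engine-vs-reference-
simulator equivalence checks.  Generated sessions may livelock (chains of
immediately-firing rules) or run to the time cap — both are legitimate
outcomes the two executors must agree on.
"""

from __future__ import annotations

import numpy as np

from .task_model import (
    ComponentDef,
    GlobalVariable,
    HardwareProfile,
    OutputAction,
    SessionDef,
    StateDef,
    TransitionRule,
    VarAction,
    validate_session,
)
from .engine import InputTrace

_FUZZ_PROFILE = HardwareProfile("fuzz", n_inputs=3, n_outputs=3,
                                max_states=None)


def random_session(rng: np.random.Generator, max_states: int = 6,
                   max_vars: int = 2) -> SessionDef:
    """A random small valid session over a 3-in/3-out profile."""
    n_states = int(rng.integers(1, max_states + 1))
    n_vars = int(rng.integers(0, max_vars + 1))
    var_names = [f"v{i}" for i in range(n_vars)]
    state_names = [f"s{i}" for i in range(n_states)]
    targets = state_names + ["next_component", "session_exit"]

    def rand_expr() -> str:
        kind = rng.integers(0, 4)
        if kind == 0 or not var_names:
            return str(rng.integers(0, 5))
        v = var_names[rng.integers(0, len(var_names))]
        if kind == 1:
            return f"{v} + {rng.integers(1, 3)}"
        if kind == 2:
            return f"rand_int(0, {rng.integers(1, 4)})"
        return f"{v} * {rng.integers(0, 3)}"

    def rand_cond() -> str:
        if not var_names:
            return "1" if rng.random() < 0.3 else "0"
        v = var_names[rng.integers(0, len(var_names))]
        op = ["<", "<=", "==", ">=", ">"][rng.integers(0, 5)]
        return f"{v} {op} {rng.integers(0, 6)}"

    states = []
    for name in state_names:
        outputs = []
        if rng.random() < 0.4:
            outputs.append(OutputAction(
                channel=int(rng.integers(1, 4)),
                pattern="pulse",
                duration_ms=int(rng.integers(1, 60)),
                cancel_on_exit=bool(rng.random() < 0.3),
            ))
        var_actions = []
        if var_names and rng.random() < 0.5:
            var_actions.append(VarAction(
                var_names[rng.integers(0, len(var_names))], rand_expr()))

        rules: list[TransitionRule] = []
        if rng.random() < 0.3:
            rules.append(TransitionRule(
                "when_count", targets[rng.integers(0, len(targets))],
                threshold=int(rng.integers(1, 5))))
        if rng.random() < 0.4:
            rules.append(TransitionRule(
                "when_var", targets[rng.integers(0, len(targets))],
                condition=rand_cond()))
        n_pins = int(rng.integers(0, 3))
        for _ in range(n_pins):
            rules.append(TransitionRule(
                "when_pin", targets[rng.integers(0, len(targets))],
                channel=int(rng.integers(1, 4)),
                level_triggered=bool(rng.random() < 0.2)))
        if rng.random() < 0.8:
            rules.append(TransitionRule(
                "when_time", targets[rng.integers(0, len(targets))],
                duration_ms=int(rng.integers(1, 80))))
        states.append(StateDef(name, outputs=tuple(outputs),
                               var_actions=tuple(var_actions),
                               transitions=tuple(rules)))

    # split states into 1-2 components
    if n_states > 1 and rng.random() < 0.5:
        cut = int(rng.integers(1, n_states))
        comps = [ComponentDef("c0", tuple(states[:cut])),
                 ComponentDef("c1", tuple(states[cut:]))]
    else:
        comps = [ComponentDef("c0", tuple(states))]

    session = SessionDef(
        name="fuzz",
        profile=_FUZZ_PROFILE,
        variables=tuple(GlobalVariable(v, int(rng.integers(0, 4)))
                        for v in var_names),
        components=tuple(comps),
    )
    assert not validate_session(session), "generator produced invalid session"
    return session


def random_trace(rng: np.random.Generator, horizon_ms: int = 400,
                 n_channels: int = 3, max_edges: int = 30) -> InputTrace:
    """Random alternating edge schedule over ``n_channels`` input lines."""
    per_channel: list[tuple[int, int, int]] = []
    for ch in range(1, n_channels + 1):
        n = int(rng.integers(0, max_edges // n_channels + 1))
        if n == 0:
            continue
        times = np.sort(rng.choice(horizon_ms, size=min(n, horizon_ms),
                                   replace=False))
        for i, t in enumerate(times):
            per_channel.append((int(t), ch, 1 if i % 2 == 0 else 0))
    per_channel.sort(key=lambda e: (e[0], e[1], e[2]))
    return InputTrace(per_channel)
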