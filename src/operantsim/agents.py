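"""Simulated subjects that close the loop around the engine.

An agent observes the events the engine emits at each virtual instant (TTL
output edges and state entries/exits) and returns future input edges — lick
contacts on the task's input channels.  Causality is enforced by the engine:
returned edges are scheduled no earlier than the next millisecond.  All agent
randomness flows from the single generator owned by the run, so a
(session, agent, seed) triple reproduces byte-identical logs.

Three agent families:

``GoNoGoAgent``
    Licks after the go cue with probability ``p_hit`` and after the no-go cue
    with ``p_fa``; the first-lick latency is a truncated normal (floor 50 ms)
    and a decision produces a lick bout at ``lick_rate_hz`` (capped at the
    murine physiological ceiling of 15 Hz).

``ChoiceHistoryAgent``
    A stochastic chooser for the switching task whose log-odds of choosing
    the left port are ``bias + Σ_i w_rewarded[i]·r_i + Σ_i w_unrewarded[i]·u_i``
    over the previous five trials, where ``r_i`` is the signed past choice
    (+1 left, −1 right) if trial ``t−i`` was rewarded and 0 otherwise, and
    ``u_i`` is the complement for unrewarded trials.  Saturating the lag-1
    weights yields a pure win-stay/lose-shift strategy (:func:`wsls_agent`).

``OracleAgent``
    Always chooses the currently rewarded port; it reads the scheduler's
    ground-truth ``side`` variable through the engine view.  Used to calibrate
    estimators (reward fraction, block statistics) free of choice noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import tasks
from .engine import EngineConfig, InputTrace, RunResult, SessionRunner
from .event_log import KIND_OUT, KIND_STATE
from .task_model import SessionDef

#: Physiological ceiling on murine lick rate (Hz); inter-lick gap >= 1000/15 ms.
MAX_LICK_RATE_HZ = 15


class ChannelMapError(ValueError):
    """Agent and session disagree about channels or task structure."""


def _lick(t: int, channel: int, contact_ms: int) -> list[tuple[int, int, int]]:
    return [(t, channel, 1), (t + contact_ms, channel, 0)]


@dataclass
class GoNoGoAgentParams:
    p_hit: float = 0.95
    p_fa: float = 0.05
    latency_mean_ms: float = 300.0
    latency_sd_ms: float = 100.0
    latency_floor_ms: int = 50
    lick_rate_hz: float = 8.0
    bout_licks: int = 5
    lick_contact_ms: int = 30

    def validate(self) -> None:
        for name in ("p_hit", "p_fa"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.lick_rate_hz <= MAX_LICK_RATE_HZ:
            raise ValueError(f"lick_rate_hz must lie in (0, {MAX_LICK_RATE_HZ}]")
        if self.latency_sd_ms <= 0 or self.bout_licks < 1:
            raise ValueError("latency_sd_ms must be > 0 and bout_licks >= 1")


def learning_trajectory(n_sessions: int, *, start=(0.8, 0.4), end=(0.95, 0.05),
                        rate: float = 0.5) -> list[GoNoGoAgentParams]:
    """Synthetic across-session learning fixture: exponential approach of
    (p_hit, p_fa) from *start* toward *end*.  Purely a test/demo fixture, not
    a claim about real acquisition dynamics."""
    out = []
    for k in range(n_sessions):
        f = 1.0 - math.exp(-rate * k)
        out.append(GoNoGoAgentParams(
            p_hit=start[0] + (end[0] - start[0]) * f,
            p_fa=start[1] + (end[1] - start[1]) * f,
        ))
    return out


class GoNoGoAgent:
    """Cue-triggered licker for the Go/No-Go task."""

    def __init__(self, params: GoNoGoAgentParams | None = None,
                 task_params: tasks.GoNoGoParams | None = None):
        self.params = params or GoNoGoAgentParams()
        self.params.validate()
        self.task_params = task_params or tasks.GoNoGoParams()
        ch = self.task_params.channels
        self._tone = ch["tone_out"]
        self._light = ch["light_out"]
        self._lick_in = ch["lick_in"]

    def check_compatible(self, session: SessionDef) -> None:
        names = set(session.state_names())
        needed = {tasks.S_GO_CUE, tasks.S_NOGO_CUE}
        if not needed <= names:
            raise ChannelMapError(
                f"session {session.name!r} lacks the Go/No-Go cue states "
                f"{sorted(needed - names)}")
        used = {a.channel for _, s in session.iter_states() for a in s.outputs}
        if self._tone not in used or self._light not in used:
            raise ChannelMapError(
                f"session {session.name!r} never drives the agent's cue "
                f"channels (tone={self._tone}, light={self._light})")
        if not 1 <= self._lick_in <= session.profile.n_inputs:
            raise ChannelMapError(f"lick channel {self._lick_in} outside the "
                                  f"profile's input range")

    def _sample_latency(self, rng: np.random.Generator) -> int:
        p = self.params
        a = (p.latency_floor_ms - p.latency_mean_ms) / p.latency_sd_ms
        x = stats.truncnorm.rvs(a, np.inf, loc=p.latency_mean_ms,
                                scale=p.latency_sd_ms, random_state=rng)
        return int(round(x))

    def _bout(self, t0: int) -> list[tuple[int, int, int]]:
        period = max(int(round(1000.0 / self.params.lick_rate_hz)),
                     int(math.ceil(1000.0 / MAX_LICK_RATE_HZ)))
        edges = []
        for k in range(self.params.bout_licks):
            edges.extend(_lick(t0 + k * period, self._lick_in,
                               min(self.params.lick_contact_ms, period - 1)))
        return edges

    def respond(self, now_ms, events, view, rng):
        edges: list[tuple[int, int, int]] = []
        for ev in events:
            if ev.kind != KIND_OUT or ev.value != 1:
                continue
            if ev.id == self._tone:
                p = self.params.p_hit
            elif ev.id == self._light:
                p = self.params.p_fa
            else:
                continue
            if rng.random() < p:
                edges.extend(self._bout(now_ms + self._sample_latency(rng)))
        return edges


@dataclass
class ChoiceHistoryAgentParams:
    bias: float = 0.0
    w_rewarded: tuple[float, ...] = (0.0,) * 5
    w_unrewarded: tuple[float, ...] = (0.0,) * 5
    poke_delay_min_ms: int = 150
    poke_delay_max_ms: int = 400
    lick_contact_ms: int = 30

    def validate(self) -> None:
        if len(self.w_rewarded) != 5 or len(self.w_unrewarded) != 5:
            raise ValueError("history weight vectors must have length 5")
        if not 1 <= self.poke_delay_min_ms <= self.poke_delay_max_ms:
            raise ValueError("need 1 <= poke_delay_min_ms <= poke_delay_max_ms")


class _SwitchTaskAgent:
    """Shared plumbing: poke center on trial start, side port on choice cue."""

    def __init__(self, task_params: tasks.ProbSwitchParams | None = None):
        self.task_params = task_params or tasks.ProbSwitchParams()
        ch = self.task_params.channels
        self._center = ch["center_in"]
        self._left = ch["left_in"]
        self._right = ch["right_in"]
        self._left_valve = ch["left_valve_out"]
        self._right_valve = ch["right_valve_out"]

    def check_compatible(self, session: SessionDef) -> None:
        names = set(session.state_names())
        needed = {tasks.S_INIT_TRIAL, tasks.S_WAIT_CHOICE}
        if not needed <= names:
            raise ChannelMapError(
                f"session {session.name!r} lacks the switching-task states "
                f"{sorted(needed - names)}")
        n_in = session.profile.n_inputs
        for ch in (self._center, self._left, self._right):
            if not 1 <= ch <= n_in:
                raise ChannelMapError(f"poke channel {ch} outside the "
                                      f"profile's input range 1..{n_in}")

    def _delay(self, rng) -> int:
        p = self.params  # type: ignore[attr-defined]
        return int(rng.integers(p.poke_delay_min_ms, p.poke_delay_max_ms + 1))

    def choose_left(self, view, rng) -> bool:  # pragma: no cover - abstract
        raise NotImplementedError

    def _on_trial_start(self, now_ms, view, rng):
        return []

    def respond(self, now_ms, events, view, rng):
        edges: list[tuple[int, int, int]] = []
        contact = self.params.lick_contact_ms  # type: ignore[attr-defined]
        for ev in events:
            if ev.kind == KIND_OUT and ev.value == 1 \
                    and ev.id in (self._left_valve, self._right_valve):
                self._saw_reward = True
            elif ev.kind == KIND_STATE and ev.value == "enter":
                if ev.id == tasks.S_INIT_TRIAL:
                    edges.extend(self._on_trial_start(now_ms, view, rng))
                    edges.extend(_lick(now_ms + self._delay(rng),
                                       self._center, contact))
                elif ev.id == tasks.S_WAIT_CHOICE:
                    left = self.choose_left(view, rng)
                    self._note_choice(left)
                    port = self._left if left else self._right
                    edges.extend(_lick(now_ms + self._delay(rng), port, contact))
        return edges

    def _note_choice(self, left: bool) -> None:
        pass


class ChoiceHistoryAgent(_SwitchTaskAgent):
    """Logistic chooser driven by bias plus 5-trial reward/no-reward history."""

    def __init__(self, params: ChoiceHistoryAgentParams | None = None,
                 task_params: tasks.ProbSwitchParams | None = None):
        super().__init__(task_params)
        self.params = params or ChoiceHistoryAgentParams()
        self.params.validate()
        self.history: list[tuple[int, bool]] = []  # (choice ±1, rewarded)
        self._pending_choice: int | None = None
        self._saw_reward = False

    def reset(self) -> None:
        self.history.clear()
        self._pending_choice = None
        self._saw_reward = False

    def _on_trial_start(self, now_ms, view, rng):
        if self._pending_choice is not None:
            self.history.append((self._pending_choice, self._saw_reward))
        self._pending_choice = None
        self._saw_reward = False
        return []

    def p_left(self) -> float:
        logit = self.params.bias
        for i in range(1, 6):
            if i > len(self.history):
                break
            choice, rewarded = self.history[-i]
            w = (self.params.w_rewarded[i - 1] if rewarded
                 else self.params.w_unrewarded[i - 1])
            logit += w * choice
        return 1.0 / (1.0 + math.exp(-logit))

    def choose_left(self, view, rng) -> bool:
        return bool(rng.random() < self.p_left())

    def _note_choice(self, left: bool) -> None:
        self._pending_choice = 1 if left else -1


def wsls_agent(task_params: tasks.ProbSwitchParams | None = None,
               saturation: float = 10.0) -> ChoiceHistoryAgent:
    """Pure win-stay/lose-shift: ±`saturation` log-odds on the previous trial
    only (a finite stand-in for ±∞)."""
    return ChoiceHistoryAgent(
        ChoiceHistoryAgentParams(
            bias=0.0,
            w_rewarded=(saturation, 0.0, 0.0, 0.0, 0.0),
            w_unrewarded=(-saturation, 0.0, 0.0, 0.0, 0.0),
        ),
        task_params,
    )


class OracleAgent(_SwitchTaskAgent):
    """Always chooses the currently rewarded port (reads the scheduler's
    ``side`` variable); no free parameters."""

    def __init__(self, task_params: tasks.ProbSwitchParams | None = None):
        super().__init__(task_params)
        self.params = ChoiceHistoryAgentParams()  # reuse delay/contact fields
        self._saw_reward = False

    def check_compatible(self, session: SessionDef) -> None:
        super().check_compatible(session)
        if "side" not in {v.name for v in session.variables}:
            raise ChannelMapError("oracle agent needs the scheduler's 'side' "
                                  "variable")

    def choose_left(self, view, rng) -> bool:
        return int(view.variables["side"]) == tasks.SIDE_LEFT


def simulate_session(session: SessionDef, agent, config: EngineConfig,
                     extra_inputs: InputTrace | None = None) -> RunResult:
    """Closed-loop run of *session* with *agent*; deterministic given the seed.

    ``extra_inputs`` merges a prerecorded edge schedule (e.g. noise on an
    unused connected channel) into the agent-driven run.
    """
    if hasattr(agent, "check_compatible"):
        agent.check_compatible(session)
    if hasattr(agent, "reset"):
        agent.reset()  # agents carry per-run history; start clean
    runner = SessionRunner(session, config, trace=extra_inputs, agent=agent)
    return runner.run()
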