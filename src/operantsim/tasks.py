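"""Parametrized builders for the two showcase operant tasks.

Both builders emit plain :class:`~operantsim.task_model.SessionDef` machines
that validate under the 20-state low-end board profile, use canonical state
names (module constants below) that the analysis layer keys on, and drive all
stochastic choices (trial type, reward lottery, block lengths) through the
expression mini-language so a run is fully determined by the engine seed.

Go/No-Go
    A trial-type lottery selects the go component (tone cue; a lick within
    cue + response window earns a water pulse) or the no-go component (light
    cue; a lick earns an air puff, withholding is a correct rejection).  An
    entry counter on the ``select`` state ends the session after ``n_trials``
    without emitting an extra trial's stimuli.

Probabilistic switching (spatial two-alternative, "2AFPC")
    The subject pokes the center port to start a trial, then a side port.
    Only one side is correct at a time and correct choices are rewarded with
    probability ``p_reward`` (percent; 75 by default).  Blocks last a uniform
    random 7-14 *rewarded* trials and the correct side reverses only after a
    rewarded trial.  If the previous ``miss_cap`` (default 2) consecutive
    trials delivered no reward, the availability lottery for the current trial
    is forced to "available" (the weakest intervention that bounds reward
    droughts); trials without reward end in a timeout punishment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .task_model import (
    ComponentDef,
    GlobalVariable,
    OutputAction,
    SessionDef,
    StateDef,
    UNO,
    VarAction,
    when_count,
    when_pin,
    when_time,
    when_var,
)

GONOGO_SESSION = "gonogo"
PROBSWITCH_SESSION = "probswitch"

# canonical Go/No-Go state names
S_SELECT = "select"
S_GO_CUE = "go_cue"
S_GO_WINDOW = "go_window"
S_GO_REWARD = "go_reward"
S_GO_MISS = "go_miss"
S_GO_ITI = "go_iti"
S_NOGO_CUE = "nogo_cue"
S_NOGO_WINDOW = "nogo_window"
S_NOGO_FA = "nogo_fa"
S_NOGO_CR = "nogo_cr"
S_NOGO_ITI = "nogo_iti"

# canonical probabilistic-switching state names
S_SETUP = "setup"
S_INIT_TRIAL = "init_trial"
S_WAIT_CHOICE = "wait_choice"
S_CHOSE_LEFT = "chose_left"
S_CHOSE_RIGHT = "chose_right"
S_REWARD_LEFT = "reward_left"
S_REWARD_RIGHT = "reward_right"
S_SWITCH_BLOCK = "switch_block"
S_NO_REWARD = "no_reward"
S_ITI = "iti"

#: Variable encoding of the correct side in the switching task.
SIDE_LEFT = 1
SIDE_RIGHT = 2


def _default_gonogo_channels() -> dict[str, int]:
    return {"lick_in": 1, "tone_out": 1, "light_out": 2,
            "water_out": 3, "airpuff_out": 4}


def _default_probswitch_channels() -> dict[str, int]:
    return {"center_in": 1, "left_in": 2, "right_in": 3,
            "left_valve_out": 1, "right_valve_out": 2}


def _check_collisions(channels: dict[str, int]) -> None:
    ins = [v for k, v in channels.items() if k.endswith("_in")]
    outs = [v for k, v in channels.items() if k.endswith("_out")]
    if len(set(ins)) != len(ins) or len(set(outs)) != len(outs):
        raise ValueError(f"channel collision in channel map: {channels}")


@dataclass
class GoNoGoParams:
    n_trials: int = 500
    p_go: float = 0.5
    cue_ms: int = 1000
    response_window_ms: int = 1500
    reward_ms: int = 50
    punish_ms: int = 200
    iti_ms: int = 3000
    channels: dict[str, int] = field(default_factory=_default_gonogo_channels)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.p_go <= 1.0:
            raise ValueError(f"p_go must lie in [0, 1], got {self.p_go}")
        pct = self.p_go * 100
        if abs(pct - round(pct)) > 1e-9:
            raise ValueError("p_go must be a whole-percent fraction "
                             "(the trial lottery draws integer percents)")
        for name in ("cue_ms", "response_window_ms", "reward_ms",
                     "punish_ms", "iti_ms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive duration")
        _check_collisions(self.channels)


@dataclass
class ProbSwitchParams:
    n_trials: int = 500
    p_reward: int = 75              # percent
    block_min: int = 7              # rewarded trials per block
    block_max: int = 14
    miss_cap: int = 2               # max consecutive unrewarded trials
    enable_miss_cap: bool = True    # disable for unbiased p_reward estimation
    timeout_ms: int = 4000
    iti_ms: int = 3000
    drink_ms: int = 500
    reward_size_left_ms: int = 40   # valve-open duration
    reward_size_right_ms: int = 40
    channels: dict[str, int] = field(
        default_factory=_default_probswitch_channels)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.p_reward <= 100:
            raise ValueError(f"p_reward must lie in (0, 100], got {self.p_reward}")
        if int(self.p_reward) != self.p_reward:
            raise ValueError("p_reward must be an integer percent")
        if not 1 <= self.block_min <= self.block_max:
            raise ValueError("need 1 <= block_min <= block_max")
        if self.miss_cap < 1:
            raise ValueError("miss_cap must be >= 1")
        for name in ("timeout_ms", "iti_ms", "drink_ms",
                     "reward_size_left_ms", "reward_size_right_ms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive duration")
        _check_collisions(self.channels)


def build_go_nogo(params: GoNoGoParams | None = None) -> SessionDef:
    """Session graph for the Go/No-Go task (11 states, fits the UNO budget)."""
    p = params or GoNoGoParams()
    p.validate()
    ch = p.channels
    pct_go = int(round(p.p_go * 100))

    select = StateDef(
        S_SELECT,
        var_actions=[VarAction("is_go", f"rand_bernoulli_pct({pct_go})")],
        transitions=[
            when_count(p.n_trials + 1, "session_exit"),
            when_var("is_go == 1", S_GO_CUE),
            when_var("is_go == 0", S_NOGO_CUE),
        ],
    )
    go = ComponentDef("go_trial", [
        select,
        StateDef(S_GO_CUE,
                 outputs=[OutputAction(ch["tone_out"], "pulse", p.cue_ms)],
                 transitions=[when_pin(ch["lick_in"], S_GO_REWARD),
                              when_time(p.cue_ms, S_GO_WINDOW)]),
        StateDef(S_GO_WINDOW,
                 transitions=[when_pin(ch["lick_in"], S_GO_REWARD),
                              when_time(p.response_window_ms, S_GO_MISS)]),
        StateDef(S_GO_REWARD,
                 outputs=[OutputAction(ch["water_out"], "pulse", p.reward_ms)],
                 transitions=[when_time(p.reward_ms, S_GO_ITI)]),
        StateDef(S_GO_MISS, transitions=[when_var("1", S_GO_ITI)]),
        StateDef(S_GO_ITI, transitions=[when_time(p.iti_ms, S_SELECT)]),
    ])
    nogo = ComponentDef("nogo_trial", [
        StateDef(S_NOGO_CUE,
                 outputs=[OutputAction(ch["light_out"], "pulse", p.cue_ms)],
                 transitions=[when_pin(ch["lick_in"], S_NOGO_FA),
                              when_time(p.cue_ms, S_NOGO_WINDOW)]),
        StateDef(S_NOGO_WINDOW,
                 transitions=[when_pin(ch["lick_in"], S_NOGO_FA),
                              when_time(p.response_window_ms, S_NOGO_CR)]),
        StateDef(S_NOGO_FA,
                 outputs=[OutputAction(ch["airpuff_out"], "pulse", p.punish_ms)],
                 transitions=[when_time(p.punish_ms, S_NOGO_ITI)]),
        StateDef(S_NOGO_CR, transitions=[when_var("1", S_NOGO_ITI)]),
        StateDef(S_NOGO_ITI, transitions=[when_time(p.iti_ms, S_SELECT)]),
    ])
    return SessionDef(
        GONOGO_SESSION,
        profile=UNO,
        variables=[GlobalVariable("is_go", 0)],
        components=[go, nogo],
    )


def build_prob_switch(params: ProbSwitchParams | None = None) -> SessionDef:
    """Session graph for the probabilistic-switching task (10 states)."""
    p = params or ProbSwitchParams()
    p.validate()
    ch = p.channels

    init_vars = [VarAction("avail", f"rand_bernoulli_pct({int(p.p_reward)})")]
    if p.enable_miss_cap:
        # force availability once miss_cap consecutive trials went unrewarded
        init_vars.append(
            VarAction("avail", f"avail + (1 - avail) * (miss_run >= {p.miss_cap})"))

    states = [
        StateDef(S_SETUP,
                 var_actions=[VarAction("side", "1 + rand_bernoulli_pct(50)"),
                              VarAction("block_left",
                                        f"rand_int({p.block_min}, {p.block_max})")],
                 transitions=[when_var("1", S_INIT_TRIAL)]),
        StateDef(S_INIT_TRIAL,
                 var_actions=init_vars,
                 transitions=[when_count(p.n_trials + 1, "session_exit"),
                              when_pin(ch["center_in"], S_WAIT_CHOICE)]),
        StateDef(S_WAIT_CHOICE,
                 transitions=[when_pin(ch["left_in"], S_CHOSE_LEFT),
                              when_pin(ch["right_in"], S_CHOSE_RIGHT)]),
        StateDef(S_CHOSE_LEFT,
                 var_actions=[VarAction("rewarded", f"avail * (side == {SIDE_LEFT})")],
                 transitions=[when_var("rewarded == 1", S_REWARD_LEFT),
                              when_var("1", S_NO_REWARD)]),
        StateDef(S_CHOSE_RIGHT,
                 var_actions=[VarAction("rewarded", f"avail * (side == {SIDE_RIGHT})")],
                 transitions=[when_var("rewarded == 1", S_REWARD_RIGHT),
                              when_var("1", S_NO_REWARD)]),
        StateDef(S_REWARD_LEFT,
                 outputs=[OutputAction(ch["left_valve_out"], "pulse",
                                       p.reward_size_left_ms)],
                 var_actions=[VarAction("miss_run", "0"),
                              VarAction("block_left", "block_left - 1")],
                 transitions=[when_var("block_left == 0", S_SWITCH_BLOCK),
                              when_time(p.drink_ms, S_ITI)]),
        StateDef(S_REWARD_RIGHT,
                 outputs=[OutputAction(ch["right_valve_out"], "pulse",
                                       p.reward_size_right_ms)],
                 var_actions=[VarAction("miss_run", "0"),
                              VarAction("block_left", "block_left - 1")],
                 transitions=[when_var("block_left == 0", S_SWITCH_BLOCK),
                              when_time(p.drink_ms, S_ITI)]),
        StateDef(S_SWITCH_BLOCK,
                 var_actions=[VarAction("side", "3 - side"),
                              VarAction("block_left",
                                        f"rand_int({p.block_min}, {p.block_max})")],
                 transitions=[when_time(p.drink_ms, S_ITI)]),
        StateDef(S_NO_REWARD,
                 var_actions=[VarAction("miss_run", "miss_run + 1")],
                 transitions=[when_time(p.timeout_ms, S_ITI)]),
        StateDef(S_ITI, transitions=[when_time(p.iti_ms, S_INIT_TRIAL)]),
    ]
    return SessionDef(
        PROBSWITCH_SESSION,
        profile=UNO,
        variables=[GlobalVariable("side", 0),
                   GlobalVariable("block_left", 0),
                   GlobalVariable("avail", 0),
                   GlobalVariable("miss_run", 0),
                   GlobalVariable("rewarded", 0)],
        components=[ComponentDef("task", states)],
    )
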