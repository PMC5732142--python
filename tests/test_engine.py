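"""Engine semantics: timers, edges, priorities, pulses, determinism, and
equivalence with the 1-ms-tick reference simulator."""

import numpy as np
import pytest

from operantsim import (
    ComponentDef,
    EngineConfig,
    EngineRunError,
    GlobalVariable,
    InputTrace,
    OutputAction,
    SessionDef,
    StateDef,
    UNLIMITED,
    VarAction,
    reference_tick_simulator,
    run_session,
    when_count,
    when_pin,
    when_time,
    when_var,
)
from operantsim import testing
from operantsim.engine import SessionRunner, read_trace, write_trace
from operantsim.task_model import TransitionRule
from operantsim.event_log import KIND_IN, KIND_OUT, KIND_STATE, Event, dumps


def one_component(*states) -> SessionDef:
    return SessionDef("t", profile=UNLIMITED,
                      components=[ComponentDef("c", list(states))])


def state_events(result):
    return [(e.time_ms, e.id, e.value) for e in result.log.events
            if e.kind == KIND_STATE]


def test_timer_only_state():
    s = one_component(StateDef("a", transitions=[when_time(100, "session_exit")]))
    r = run_session(s, None, EngineConfig(seed=0))
    assert r.exit_reason == "session_exit"
    assert r.log.events == [Event(0, KIND_STATE, "a", "enter"),
                            Event(100, KIND_STATE, "a", "exit")]


def test_single_input_edge_transition():
    s = one_component(
        StateDef("a", transitions=[when_pin(1, "b")]),
        StateDef("b", transitions=[when_time(10, "session_exit")]),
    )
    r = run_session(s, InputTrace([(50, 1, 1), (60, 1, 0)]), EngineConfig(seed=0))
    assert state_events(r) == [(0, "a", "enter"), (50, "a", "exit"),
                               (50, "b", "enter"), (60, "b", "exit")]


def test_entry_counter_alternation():
    """A<->B timers with an entry-count exit on A: hand-enumerated event list."""
    s = one_component(
        StateDef("A", transitions=[when_count(3, "session_exit"),
                                   when_time(10, "B")]),
        StateDef("B", transitions=[when_time(10, "A")]),
    )
    r = run_session(s, None, EngineConfig(seed=0))
    assert r.exit_reason == "session_exit"
    assert r.end_time_ms == 40
    expected = [(0, "A", "enter"), (10, "A", "exit"),
                (10, "B", "enter"), (20, "B", "exit"),
                (20, "A", "enter"), (30, "A", "exit"),
                (30, "B", "enter"), (40, "B", "exit"),
                (40, "A", "enter"), (40, "A", "exit")]  # 3rd entry: 0-duration
    assert state_events(r) == expected
    oracle = reference_tick_simulator(s, None, EngineConfig(seed=0))
    assert oracle.log.events == r.log.events


def test_pulse_outlives_its_state():
    s = one_component(
        StateDef("a", outputs=[OutputAction(1, "pulse", 200)],
                 transitions=[when_time(50, "b")]),
        StateDef("b", transitions=[when_time(500, "session_exit")]),
    )
    r = run_session(s, None, EngineConfig(seed=0))
    outs = [(e.time_ms, e.value) for e in r.log.events if e.kind == KIND_OUT]
    assert outs == [(0, 1), (200, 0)]  # off fires while b is active
    assert reference_tick_simulator(s, None, EngineConfig(seed=0)).log.events \
        == r.log.events


def test_cancel_on_exit_truncates_the_pulse():
    s = one_component(
        StateDef("a", outputs=[OutputAction(1, "pulse", 200,
                                            cancel_on_exit=True)],
                 transitions=[when_time(50, "b")]),
        StateDef("b", transitions=[when_time(500, "session_exit")]),
    )
    r = run_session(s, None, EngineConfig(seed=0))
    outs = [(e.time_ms, e.value) for e in r.log.events if e.kind == KIND_OUT]
    assert outs == [(0, 1), (50, 0)]


def test_when_count_beats_simultaneous_when_pin():
    """Both conditions hold at the entry instant; entry-count has priority."""
    def session(a_rules):
        return one_component(
            StateDef("s0", transitions=[when_time(5, "a")]),
            StateDef("a", transitions=a_rules),
            StateDef("b", transitions=[when_time(10, "session_exit")]),
            StateDef("c", transitions=[when_time(10, "session_exit")]),
        )
    trace = InputTrace([(3, 1, 1)])  # channel high before and at a's entry
    with_count = session([when_count(1, "c"),
                          when_pin(1, "b", level_triggered=True)])
    r = run_session(with_count, trace, EngineConfig(seed=0))
    assert (5, "c", "enter") in state_events(r)
    without_count = session([when_pin(1, "b", level_triggered=True)])
    r2 = run_session(without_count, trace, EngineConfig(seed=0))
    assert (5, "b", "enter") in state_events(r2)


def test_simultaneous_pin_edges_lowest_channel_wins():
    s = one_component(
        StateDef("a", transitions=[when_pin(2, "b"), when_pin(1, "c")]),
        StateDef("b", transitions=[when_time(10, "session_exit")]),
        StateDef("c", transitions=[when_time(10, "session_exit")]),
    )
    r = run_session(s, InputTrace([(5, 1, 1), (5, 2, 1)]), EngineConfig(seed=0))
    assert (5, "c", "enter") in state_events(r)


def test_stateless_state_persists_to_time_cap():
    s = one_component(StateDef("a"))
    r = run_session(s, None, EngineConfig(seed=0, max_virtual_time_ms=500))
    assert r.exit_reason == "time_cap"
    assert state_events(r) == [(0, "a", "enter"), (500, "a", "exit")]


def test_edge_before_entry_does_not_fire_unless_level_triggered():
    def session(level_triggered):
        return one_component(
            StateDef("a", transitions=[when_time(5, "b")]),
            StateDef("b", transitions=[
                when_pin(1, "c", level_triggered=level_triggered),
                when_time(100, "session_exit")]),
            StateDef("c", transitions=[when_time(1, "session_exit")]),
        )
    trace = InputTrace([(3, 1, 1)])  # rises while a is active, stays high
    r_edge = run_session(session(False), trace, EngineConfig(seed=0))
    assert all(ev[1] != "c" for ev in state_events(r_edge))
    assert r_edge.end_time_ms == 105
    r_level = run_session(session(True), trace, EngineConfig(seed=0))
    assert (5, "c", "enter") in state_events(r_level)


def test_next_component_and_final_component_exit():
    s = SessionDef("nc", profile=UNLIMITED, components=[
        ComponentDef("c1", [StateDef("a", transitions=[
            when_time(10, "next_component")])]),
        ComponentDef("c2", [StateDef("b", transitions=[
            when_time(10, "next_component")])]),
    ])
    r = run_session(s, None, EngineConfig(seed=0))
    assert state_events(r) == [(0, "a", "enter"), (10, "a", "exit"),
                               (10, "b", "enter"), (20, "b", "exit")]
    assert r.exit_reason == "session_exit" and r.end_time_ms == 20


def test_divide_by_zero_is_a_run_error_naming_the_state():
    s = SessionDef("dz", profile=UNLIMITED,
                   variables=[GlobalVariable("x", 0), GlobalVariable("y", 0)],
                   components=[ComponentDef("c", [
                       StateDef("boom",
                                var_actions=[VarAction("y", "1 / x")],
                                transitions=[when_time(10, "session_exit")])])])
    with pytest.raises(EngineRunError, match="boom"):
        run_session(s, None, EngineConfig(seed=0))


def test_when_var_livelock_is_detected():
    s = one_component(
        StateDef("a", transitions=[when_var("1", "b")]),
        StateDef("b", transitions=[when_var("1", "a")]),
    )
    with pytest.raises(EngineRunError, match="livelock"):
        run_session(s, None, EngineConfig(seed=0))
    with pytest.raises(EngineRunError, match="livelock"):
        reference_tick_simulator(s, None, EngineConfig(seed=0))


def test_variable_driven_durations_and_thresholds():
    s = SessionDef(
        "varref", profile=UNLIMITED,
        variables=[GlobalVariable("d", 25), GlobalVariable("n", 2)],
        components=[ComponentDef("c", [
            StateDef("a", transitions=[
                TransitionRule("when_count", "session_exit", threshold="n"),
                when_time("d", "a")])])])
    r = run_session(s, None, EngineConfig(seed=0))
    assert r.end_time_ms == 25  # exits on the 2nd entry, after one 25 ms visit


def test_run_result_is_deterministic_and_byte_identical():
    rng = np.random.default_rng(77)
    sess = testing.random_session(rng)
    trace = testing.random_trace(rng)
    cfg = EngineConfig(seed=5, max_virtual_time_ms=300)
    try:
        a = run_session(sess, trace, cfg)
        b = run_session(sess, trace, cfg)
    except EngineRunError:
        pytest.skip("fuzz draw produced a livelocking session")
    assert dumps(a.log) == dumps(b.log)
    assert a.final_variables == b.final_variables


def test_state_intervals_partition_the_run(wsls_trials, wsls_session):
    # structural check on a long closed-loop log
    from operantsim.agents import simulate_session, wsls_agent

    r = simulate_session(wsls_session, wsls_agent(), EngineConfig(seed=11))
    states = [e for e in r.log.events if e.kind == KIND_STATE]
    assert states[0] == Event(0, KIND_STATE, states[0].id, "enter")
    t_cursor = 0
    open_state = None
    for e in states:
        if e.value == "enter":
            assert open_state is None
            assert e.time_ms == t_cursor
            open_state = e.id
        else:
            assert open_state == e.id
            assert e.time_ms >= t_cursor
            t_cursor = e.time_ms
            open_state = None
    assert open_state is None
    assert t_cursor == r.end_time_ms
    assert all(isinstance(e.time_ms, int) for e in r.log.events)


def test_output_edges_balance_against_final_status():
    rng = np.random.default_rng(123)
    for k in range(20):
        srng = np.random.default_rng(6000 + k)
        sess = testing.random_session(srng)
        trace = testing.random_trace(srng)
        try:
            r = run_session(sess, trace,
                            EngineConfig(seed=k, max_virtual_time_ms=300))
        except EngineRunError:
            continue
        per_channel: dict[int, int] = {}
        for e in r.log.events:
            if e.kind == KIND_OUT:
                per_channel[e.id] = per_channel.get(e.id, 0) \
                    + (1 if e.value == 1 else -1)
        for ch, net in per_channel.items():
            assert net in (0, 1)
            assert net == r.final_outputs.get(ch, 0)


def test_engine_equals_tick_oracle_on_fuzzed_sessions():
    """Spot equivalence run (the acceptance suite runs the full 100)."""
    agree = 0
    for i in range(30):
        srng = np.random.default_rng(40_000 + i)
        sess = testing.random_session(srng)
        trace = testing.random_trace(srng)
        cfg = EngineConfig(seed=int(srng.integers(0, 2**31)),
                           max_virtual_time_ms=400)
        try:
            fast = run_session(sess, trace, cfg)
            fast_out = (fast.log.events, fast.final_variables,
                        fast.exit_reason, fast.end_time_ms)
        except EngineRunError as exc:
            fast_out = ("error", type(exc).__name__)
        try:
            slow = reference_tick_simulator(sess, trace, cfg)
            slow_out = (slow.log.events, slow.final_variables,
                        slow.exit_reason, slow.end_time_ms)
        except EngineRunError as exc:
            slow_out = ("error", type(exc).__name__)
        assert fast_out == slow_out, f"divergence on fuzz case {i}"
        agree += 1
    assert agree == 30


def test_session_runner_exposes_instant_stepping():
    s = one_component(
        StateDef("a", transitions=[when_time(10, "b")]),
        StateDef("b", transitions=[when_time(5, "session_exit")]),
    )
    runner = SessionRunner(s, EngineConfig(seed=0))
    runner.start()
    assert runner.current.name == "a" and runner.t == 0
    assert runner.advance_instant()           # t=10: a -> b
    assert runner.current.name == "b" and runner.t == 10
    assert not runner.advance_instant()       # t=15: session exit
    assert runner.exited and runner.exit_reason == "session_exit"


def test_trace_file_round_trip(tmp_path):
    trace = InputTrace([(0, 1, 1), (30, 1, 0), (30, 2, 1), (45, 2, 0)])
    path = tmp_path / "edges.tsv"
    write_trace(trace, path)
    assert read_trace(path) == trace


def test_invalid_traces_rejected():
    with pytest.raises(ValueError, match="alternate"):
        InputTrace([(0, 1, 1), (5, 1, 1)])
    with pytest.raises(ValueError, match="sorted"):
        InputTrace([(5, 1, 1), (3, 2, 1)])
    with pytest.raises(ValueError, match="negative"):
        InputTrace([(-1, 1, 1)])
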