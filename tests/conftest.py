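"""Shared fixtures: one simulation per study condition, reused across tests.

All runs are seeded; the expensive closed-loop simulations (20k-50k trials)
are session-scoped so each condition is simulated exactly once per test run.
"""

from __future__ import annotations

import pytest

from operantsim import (
    EngineConfig,
    build_go_nogo,
    build_prob_switch,
    trials_from_log,
)
from operantsim.agents import (
    ChoiceHistoryAgent,
    ChoiceHistoryAgentParams,
    GoNoGoAgent,
    GoNoGoAgentParams,
    OracleAgent,
    simulate_session,
    wsls_agent,
)
from operantsim.tasks import GoNoGoParams, ProbSwitchParams

RECOVERY_TRUTH = ChoiceHistoryAgentParams(
    bias=0.2,
    w_rewarded=(1.2, 0.8, 0.5, 0.3, 0.1),
    w_unrewarded=(-0.3, -0.2, -0.1, 0.0, 0.0),
)


@pytest.fixture(scope="session")
def gonogo_session():
    return build_go_nogo(GoNoGoParams(n_trials=500))


@pytest.fixture(scope="session")
def gonogo_run(gonogo_session):
    agent = GoNoGoAgent(GoNoGoAgentParams(p_hit=0.95, p_fa=0.05))
    return simulate_session(gonogo_session, agent, EngineConfig(seed=7))


@pytest.fixture(scope="session")
def gonogo_trials(gonogo_session, gonogo_run):
    return trials_from_log(gonogo_run.log, gonogo_session)


@pytest.fixture(scope="session")
def capped_session():
    return build_prob_switch(ProbSwitchParams(n_trials=20000))


@pytest.fixture(scope="session")
def oracle_capped_run(capped_session):
    return simulate_session(capped_session, OracleAgent(), EngineConfig(seed=101))


@pytest.fixture(scope="session")
def oracle_capped_trials(capped_session, oracle_capped_run):
    return trials_from_log(oracle_capped_run.log, capped_session)


@pytest.fixture(scope="session")
def uncapped_session():
    return build_prob_switch(
        ProbSwitchParams(n_trials=20000, enable_miss_cap=False))


@pytest.fixture(scope="session")
def oracle_uncapped_trials(uncapped_session):
    run = simulate_session(uncapped_session, OracleAgent(), EngineConfig(seed=102))
    return trials_from_log(run.log, uncapped_session)


@pytest.fixture(scope="session")
def recovery_trials(capped_session):
    agent = ChoiceHistoryAgent(RECOVERY_TRUTH)
    run = simulate_session(capped_session, agent, EngineConfig(seed=103))
    return trials_from_log(run.log, capped_session)


@pytest.fixture(scope="session")
def null_trials(capped_session):
    agent = ChoiceHistoryAgent(ChoiceHistoryAgentParams())
    run = simulate_session(capped_session, agent, EngineConfig(seed=104))
    return trials_from_log(run.log, capped_session)


@pytest.fixture(scope="session")
def calibration_trials():
    session = build_prob_switch(ProbSwitchParams(n_trials=50000))
    agent = ChoiceHistoryAgent(RECOVERY_TRUTH)
    run = simulate_session(session, agent, EngineConfig(seed=106))
    return trials_from_log(run.log, session)


@pytest.fixture(scope="session")
def p100_session():
    return build_prob_switch(ProbSwitchParams(n_trials=5000, p_reward=100))


@pytest.fixture(scope="session")
def p100_trials(p100_session):
    run = simulate_session(p100_session, OracleAgent(), EngineConfig(seed=105))
    return trials_from_log(run.log, p100_session)


@pytest.fixture(scope="session")
def wsls_session():
    return build_prob_switch(ProbSwitchParams(n_trials=600, p_reward=100))


@pytest.fixture(scope="session")
def wsls_trials(wsls_session):
    run = simulate_session(wsls_session, wsls_agent(), EngineConfig(seed=11))
    return trials_from_log(run.log, wsls_session)
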