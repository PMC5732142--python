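"""Trial segmentation and the behavioral statistics / regression layer."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from operantsim import (
    EngineConfig,
    build_go_nogo,
    build_prob_switch,
    filter_to_level,
    trials_from_log,
)
from operantsim.agents import (
    ChoiceHistoryAgent,
    ChoiceHistoryAgentParams,
    GoNoGoAgent,
    GoNoGoAgentParams,
    OracleAgent,
    simulate_session,
)
from operantsim.analysis import (
    TRIAL_COLUMNS,
    calibration_bins,
    correct_rate,
    design_matrix,
    fit_choice_history_logit,
    response_latency,
    stay_probability_by_history,
    switch_curve,
    trials_to_switch,
)
from operantsim.event_log import EventLog, KIND_STATE
from operantsim.tasks import GoNoGoParams, ProbSwitchParams
from tests.conftest import RECOVERY_TRUTH


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Hand-built trial table with sensible defaults per column."""
    filled = []
    for i, row in enumerate(rows):
        base = {"trial": i, "task": "probswitch", "cue": None, "choice": None,
                "correct_side": None, "outcome": None, "responded": True,
                "rewarded": False, "latency_ms": np.nan, "block": 0,
                "trial_in_block": i + 1}
        base.update(row)
        filled.append(base)
    return pd.DataFrame(filled, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_trial_count_is_conserved():
    session = build_go_nogo(GoNoGoParams(n_trials=100))
    run = simulate_session(session, GoNoGoAgent(), EngineConfig(seed=17))
    assert len(trials_from_log(run.log, session)) == 100


def test_level2_log_yields_trials_without_latencies(gonogo_session, gonogo_run):
    l2 = filter_to_level(gonogo_run.log, 2)
    with pytest.warns(UserWarning, match="latencies"):
        trials = trials_from_log(l2, gonogo_session)
    assert len(trials) == 500
    assert trials["latency_ms"].isna().all()
    assert set(trials["outcome"]) <= {"hit", "miss", "fa", "cr"}


def test_truncated_log_returns_only_completed_trials(gonogo_session,
                                                     gonogo_run):
    events = gonogo_run.log.events
    state_times = [e.time_ms for e in events if e.kind == KIND_STATE]
    cut = state_times[len(state_times) // 2]  # chop mid-session
    truncated = EventLog(header=dict(gonogo_run.log.header),
                         events=[e for e in events if e.time_ms < cut])
    full = trials_from_log(gonogo_run.log, gonogo_session)
    part = trials_from_log(truncated, gonogo_session)
    assert 0 < len(part) < len(full)
    pd.testing.assert_frame_equal(part, full.iloc[:len(part)])


def test_unknown_tasks_are_rejected(gonogo_run):
    from operantsim import ComponentDef, SessionDef, StateDef, when_time

    other = SessionDef("mystery", components=[ComponentDef("c", [
        StateDef("s", transitions=[when_time(1, "session_exit")])])])
    with pytest.raises(ValueError, match="unknown task"):
        trials_from_log(gonogo_run.log, other)


# ---------------------------------------------------------------------------
# Go/No-Go statistics
# ---------------------------------------------------------------------------

def test_correct_rate_by_hand_enumeration():
    rows = ([{"cue": "go", "outcome": "hit"}] * 4
            + [{"cue": "nogo", "outcome": "cr"}] * 3
            + [{"cue": "go", "outcome": "miss"}] * 2
            + [{"cue": "nogo", "outcome": "fa"}])
    assert correct_rate(make_trials(rows)) == pytest.approx(0.7)


def test_correct_rate_bounds_and_identities(gonogo_trials):
    rate = correct_rate(gonogo_trials)
    assert 0.0 <= rate <= 1.0
    go = gonogo_trials[gonogo_trials["cue"] == "go"]
    nogo = gonogo_trials[gonogo_trials["cue"] == "nogo"]
    assert (go["outcome"] == "hit").sum() + (go["outcome"] == "miss").sum() \
        == len(go)
    assert (nogo["outcome"] == "fa").sum() + (nogo["outcome"] == "cr").sum() \
        == len(nogo)


def test_correct_rate_all_correct_and_empty():
    rows = [{"cue": "go", "outcome": "hit"}, {"cue": "nogo", "outcome": "cr"}]
    assert correct_rate(make_trials(rows)) == 1.0
    with pytest.raises(ValueError):
        correct_rate(make_trials([]))


def test_latency_single_trial_and_absent_subset():
    rows = [{"cue": "go", "outcome": "hit", "responded": True,
             "latency_ms": 300.0},
            {"cue": "nogo", "outcome": "cr", "responded": False}]
    summary = response_latency(make_trials(rows))
    assert summary.loc["go", "mean"] == 300.0
    assert "nogo" not in summary.index  # absent, not zero


def test_latency_direction_go_vs_nogo():
    """An agent parameterized to be impulsive after go and patient after
    no-go shows the corresponding latency ordering."""
    session = build_go_nogo(GoNoGoParams(n_trials=150))
    # single agent: hits fast; false alarms drawn from a slower distribution
    fast = GoNoGoAgent(GoNoGoAgentParams(p_hit=0.9, p_fa=0.9,
                                         latency_mean_ms=200,
                                         latency_sd_ms=50))
    run = simulate_session(session, fast, EngineConfig(seed=23))
    trials = trials_from_log(run.log, session)
    slow_session = build_go_nogo(GoNoGoParams(n_trials=150))
    slow = GoNoGoAgent(GoNoGoAgentParams(p_hit=0.9, p_fa=0.9,
                                         latency_mean_ms=700,
                                         latency_sd_ms=50))
    run2 = simulate_session(slow_session, slow, EngineConfig(seed=23))
    trials2 = trials_from_log(run2.log, slow_session)
    assert response_latency(trials)["mean"].loc["go"] \
        < response_latency(trials2)["mean"].loc["go"]


# ---------------------------------------------------------------------------
# switching statistics
# ---------------------------------------------------------------------------

def test_switch_curve_oracle_is_a_step_function(oracle_capped_trials):
    curve = switch_curve(oracle_capped_trials, window=3, direction="to_left")
    assert (curve.loc[-3:0, "frac_left"] == 0.0).all()
    assert (curve.loc[1:, "frac_left"] == 1.0).all()


def test_switch_curve_wsls_lags_one_trial(wsls_trials):
    curve = switch_curve(wsls_trials, window=3, direction="to_left")
    assert curve.loc[0, "frac_left"] == 0.0   # rewarded trial on the old port
    assert curve.loc[1, "frac_left"] == 0.0   # win-stay: still on the old port
    assert curve.loc[2, "frac_left"] == 1.0   # lose-shift lands on the new one


def test_switch_curve_symmetry(oracle_capped_trials):
    to_left = switch_curve(oracle_capped_trials, window=3, direction="to_left")
    to_right = switch_curve(oracle_capped_trials, window=3,
                            direction="to_right")
    assert np.allclose(to_left["frac_left"], 1.0 - to_right["frac_left"])


def test_trials_to_switch_oracle_and_wsls(oracle_capped_trials, wsls_trials):
    oracle = trials_to_switch(oracle_capped_trials)
    assert oracle.loc["right_to_left", "mean"] == 1.0
    assert oracle.loc["left_to_right", "mean"] == 1.0
    wsls = trials_to_switch(wsls_trials)
    assert wsls.loc["right_to_left", "mean"] == 2.0
    assert wsls.loc["left_to_right", "mean"] == 2.0


def test_never_switching_reversal_is_excluded_with_warning():
    rows = ([{"choice": "left", "correct_side": "left", "rewarded": True,
              "block": 0}] * 3
            + [{"choice": "left", "correct_side": "right", "rewarded": False,
                "block": 1}] * 3)
    with pytest.warns(UserWarning, match="excluded"):
        result = trials_to_switch(make_trials(rows))
    assert result.empty  # the lone reversal left nothing to average
    assert result.attrs["excluded_reversals"] == 1


def test_stay_probability_by_hand_enumeration():
    seq = [("left", True), ("left", False), ("left", True), ("right", False),
           ("right", True), ("right", True), ("left", False), ("left", True)]
    trials = make_trials([{"choice": c, "rewarded": r} for c, r in seq])
    result = stay_probability_by_history(trials)
    assert result.loc["rr", "stay_fraction"] == 0.0 and result.loc["rr", "n"] == 1
    assert result.loc["ru", "stay_fraction"] == 1.0 and result.loc["ru", "n"] == 1
    assert result.loc["ur", "stay_fraction"] == 0.5 and result.loc["ur", "n"] == 2
    assert "uu" not in result.index  # no qualifying pair for that pattern


def test_stay_probability_wsls_fingerprint(wsls_trials):
    result = stay_probability_by_history(wsls_trials)
    for pattern in result.index:
        if pattern.endswith("r"):      # last trial rewarded -> stay
            assert result.loc[pattern, "stay_fraction"] > 0.98
        else:                          # last trial unrewarded -> shift
            assert result.loc[pattern, "stay_fraction"] < 0.02


# ---------------------------------------------------------------------------
# choice-history regression
# ---------------------------------------------------------------------------

def _nll(params, y, X):
    z = X @ params
    return np.sum(np.logaddexp(0, z) - y * z)


def test_fit_matches_direct_likelihood_optimization():
    """Independent oracle: scipy minimization of the exact NLL."""
    session = build_prob_switch(ProbSwitchParams(n_trials=3000))
    agent = ChoiceHistoryAgent(RECOVERY_TRUTH)
    run = simulate_session(session, agent, EngineConfig(seed=31))
    trials = trials_from_log(run.log, session)
    model = fit_choice_history_logit(trials)
    y, X = design_matrix(trials)
    direct = optimize.minimize(_nll, np.zeros(X.shape[1]), args=(y, X),
                               method="BFGS",
                               options={"gtol": 1e-8, "maxiter": 500})
    assert np.allclose(model.coefficients(), direct.x, atol=1e-4)
    assert model.log_likelihood == pytest.approx(-direct.fun, rel=1e-6)
    assert model.n == len(trials) - 5


def test_recency_gradient_is_recovered(recovery_trials):
    model = fit_choice_history_logit(recovery_trials)
    assert model.w_rewarded[0] > model.w_rewarded[4]  # lag 1 outweighs lag 5


def test_recovery_across_random_weight_vectors():
    """Median absolute coefficient error < 0.1 over random generating models
    (5 vectors x 5,000 trials)."""
    rng = np.random.default_rng(42)
    errors = []
    for k in range(5):
        truth = ChoiceHistoryAgentParams(
            bias=float(rng.uniform(-1.0, 1.0)),
            w_rewarded=tuple(rng.uniform(-1.5, 1.5, size=5)),
            w_unrewarded=tuple(rng.uniform(-1.5, 1.5, size=5)),
        )
        session = build_prob_switch(ProbSwitchParams(n_trials=5000))
        run = simulate_session(session, ChoiceHistoryAgent(truth),
                               EngineConfig(seed=300 + k))
        trials = trials_from_log(run.log, session)
        model = fit_choice_history_logit(trials)
        true_vec = np.concatenate(([truth.bias], truth.w_rewarded,
                                   truth.w_unrewarded))
        errors.extend(np.abs(model.coefficients() - true_vec))
    assert np.median(errors) < 0.1


def test_separation_raises_with_advice():
    # deterministic alternation is perfectly predicted by lag-1 history
    rows = [{"choice": "left" if i % 2 == 0 else "right", "rewarded": False}
            for i in range(200)]
    with pytest.raises(ValueError, match="l2_alpha"):
        fit_choice_history_logit(make_trials(rows))
    model = fit_choice_history_logit(make_trials(rows), l2_alpha=1.0)
    assert np.all(np.isfinite(model.coefficients()))


def test_statistics_invariant_under_left_right_relabeling(wsls_trials,
                                                          recovery_trials):
    """Relabeling ports (and negating bias/regressors) leaves every statistic
    unchanged."""
    def flip(trials):
        flipped = trials.copy()
        swap = {"left": "right", "right": "left"}
        flipped["choice"] = flipped["choice"].map(swap)
        flipped["correct_side"] = flipped["correct_side"].map(swap)
        return flipped

    flipped = flip(wsls_trials)
    orig_stay = stay_probability_by_history(wsls_trials)
    flip_stay = stay_probability_by_history(flipped)
    pd.testing.assert_frame_equal(orig_stay, flip_stay)

    orig_switch = trials_to_switch(wsls_trials)
    flip_switch = trials_to_switch(flipped)
    assert orig_switch.loc["right_to_left", "mean"] \
        == flip_switch.loc["left_to_right", "mean"]

    # regression symmetry on stochastic (non-separable) choices
    sub = recovery_trials.head(4000)
    m = fit_choice_history_logit(sub)
    mf = fit_choice_history_logit(flip(sub))
    assert mf.bias == pytest.approx(-m.bias, abs=1e-6)
    assert np.allclose(mf.w_rewarded, m.w_rewarded, atol=1e-6)
    assert np.allclose(mf.w_unrewarded, m.w_unrewarded, atol=1e-6)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_of_a_well_specified_model(calibration_trials):
    model = fit_choice_history_logit(calibration_trials)
    bins = calibration_bins(calibration_trials, model, n_bins=50)
    assert len(bins) == 50
    assert (np.abs(bins["predicted"] - bins["actual"]) < 0.05).all()


def test_calibration_single_bin_recovers_overall_fraction(recovery_trials):
    model = fit_choice_history_logit(recovery_trials)
    bins = calibration_bins(recovery_trials, model, n_bins=1)
    y, _ = design_matrix(recovery_trials)
    assert bins.loc[0, "actual"] == pytest.approx(y.mean())
    assert bins.loc[0, "predicted"] == pytest.approx(
        model.predict(recovery_trials).mean())


def test_calibration_collapses_for_constant_predictions(recovery_trials):
    from operantsim.analysis import ChoiceHistoryModel

    constant = ChoiceHistoryModel(bias=0.0, w_rewarded=np.zeros(5),
                                  w_unrewarded=np.zeros(5),
                                  log_likelihood=0.0, n=0)
    with pytest.warns(UserWarning, match="collapse"):
        bins = calibration_bins(recovery_trials, constant, n_bins=50)
    assert len(bins) == 1
    assert bins.loc[0, "predicted"] == pytest.approx(0.5)
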