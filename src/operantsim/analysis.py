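"""Trial tables and choice-behavior statistics derived from event logs.

:func:`trials_from_log` segments a Level >= 2 log of one of the built-in tasks
into a per-trial table (one row per *completed* trial).  On top of that table
the module computes the standard behavioral read-outs:

* ``correct_rate`` — (hits + correct rejections) / trials for Go/No-Go;
* ``response_latency`` — cue onset to first lick, summarized per cue type;
* ``switch_curve`` / ``trials_to_switch`` — choice fractions aligned on
  reversals of the rewarded port and the mean lag to follow a reversal
  (position 0 is the last trial of the old block — the rewarded trial that
  triggered the switch — so the lag is always >= 1);
* ``stay_probability_by_history`` — win-stay/lose-shift fingerprints
  conditioned on the reward pattern of two consecutive same-port choices;
* ``fit_choice_history_logit`` — maximum-likelihood logistic regression of
  the current choice on an intercept (intrinsic bias) plus the signed
  rewarded/unrewarded choice history of the previous five trials;
* ``calibration_bins`` — actual vs model-predicted left-choice fraction in
  equal-count bins of predicted probability.

History regressor coding (matches the simulated agents): choice c_t is +1 for
left and −1 for right; ``r_i = c_{t−i}`` if trial ``t−i`` was rewarded else 0,
``u_i = c_{t−i}`` if unrewarded else 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import tasks
from .event_log import KIND_IN, KIND_STATE, EventLog
from .task_model import SessionDef

TRIAL_COLUMNS = ["trial", "task", "cue", "choice", "correct_side", "outcome",
                 "responded", "rewarded", "latency_ms", "block",
                 "trial_in_block"]

_GONOGO_OUTCOME_STATES = {
    tasks.S_GO_REWARD: ("hit", True, True),
    tasks.S_GO_MISS: ("miss", False, False),
    tasks.S_NOGO_FA: ("fa", True, False),
    tasks.S_NOGO_CR: ("cr", False, False),
}


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TRIAL_COLUMNS)


def trials_from_log(log: EventLog, session: SessionDef) -> pd.DataFrame:
    """Segment *log* into a trial table using the session's state stream.

    Requires a log of Record Level >= 2 (state information present) from one
    of the built-in tasks; logs from unknown tasks are rejected.  Incomplete
    trailing trials (truncated logs) are dropped; choice trials without a
    side-port response are excluded from the table and counted in
    ``table.attrs["dropped_trials"]``.
    """
    if session.name == tasks.GONOGO_SESSION:
        return _gonogo_trials(log, session)
    if session.name == tasks.PROBSWITCH_SESSION:
        return _probswitch_trials(log)
    raise ValueError(f"cannot derive trials from unknown task "
                     f"{session.name!r}; expected "
                     f"{tasks.GONOGO_SESSION!r} or {tasks.PROBSWITCH_SESSION!r}")


def _gonogo_trials(log: EventLog, session: SessionDef) -> pd.DataFrame:
    if log.record_level < 2:
        raise ValueError("need a Record Level >= 2 log (state stream) to "
                         "segment trials")
    # the lick line is whatever pin the go-cue state listens on
    go_cue = session.find_state(tasks.S_GO_CUE)
    lick_ch = next(r.channel for r in go_cue.transitions
                   if r.kind == "when_pin")
    have_inputs = any(e.kind == KIND_IN for e in log.events)
    if not have_inputs:
        warnings.warn("log has no input events (Record Level 2): latencies "
                      "cannot be computed", stacklevel=2)

    licks = [e.time_ms for e in log.events
             if e.kind == KIND_IN and e.id == lick_ch and e.value == 1]
    licks_arr = np.asarray(licks, dtype=float)

    rows = []
    cue = None
    cue_time = None
    for e in log.events:
        if e.kind != KIND_STATE or e.value != "enter":
            continue
        if e.id == tasks.S_GO_CUE:
            cue, cue_time = "go", e.time_ms
        elif e.id == tasks.S_NOGO_CUE:
            cue, cue_time = "nogo", e.time_ms
        elif e.id in _GONOGO_OUTCOME_STATES and cue is not None:
            outcome, responded, rewarded = _GONOGO_OUTCOME_STATES[e.id]
            latency = np.nan
            if responded and have_inputs:
                after = licks_arr[(licks_arr >= cue_time)
                                  & (licks_arr <= e.time_ms)]
                if after.size:
                    latency = float(after[0] - cue_time)
            rows.append((len(rows), "gonogo", cue, None, None, outcome,
                         responded, rewarded, latency, 0, len(rows)))
            cue = None
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.attrs["dropped_trials"] = 0
    return df


def _probswitch_trials(log: EventLog) -> pd.DataFrame:
    if log.record_level < 2:
        raise ValueError("need a Record Level >= 2 log (state stream) to "
                         "segment trials")
    raw = []  # (choice, rewarded, switch_after, start_t, choice_t)
    cur = None
    dropped = 0
    for e in log.events:
        if e.kind != KIND_STATE or e.value != "enter":
            continue
        if e.id == tasks.S_INIT_TRIAL:
            if cur is not None:
                if cur["choice"] is not None and cur["outcome_seen"]:
                    raw.append(cur)
                else:
                    dropped += 1
            cur = {"choice": None, "rewarded": False, "switch_after": False,
                   "start_t": e.time_ms, "choice_t": None,
                   "outcome_seen": False}
        elif cur is None:
            continue
        elif e.id == tasks.S_CHOSE_LEFT:
            cur["choice"], cur["choice_t"] = "left", e.time_ms
        elif e.id == tasks.S_CHOSE_RIGHT:
            cur["choice"], cur["choice_t"] = "right", e.time_ms
        elif e.id in (tasks.S_REWARD_LEFT, tasks.S_REWARD_RIGHT):
            cur["rewarded"] = True
            cur["outcome_seen"] = True
        elif e.id == tasks.S_NO_REWARD:
            cur["outcome_seen"] = True
        elif e.id == tasks.S_SWITCH_BLOCK:
            cur["switch_after"] = True
    # an in-flight trial at log end is incomplete by construction: drop it
    if cur is not None:
        dropped += 1

    blocks = []
    block = 0
    rows = []
    for i, tr in enumerate(raw):
        rows.append((tr["choice"], tr["rewarded"], block, tr["start_t"],
                     tr["choice_t"]))
        blocks.append(block)
        if tr["switch_after"]:
            block += 1

    n_blocks = (max(blocks) + 1) if blocks else 0
    correct = _infer_correct_sides(rows, n_blocks)

    out = []
    counter: dict[int, int] = {}
    for i, (choice, rewarded, blk, start_t, choice_t) in enumerate(rows):
        counter[blk] = counter.get(blk, 0) + 1
        latency = (float(choice_t - start_t)
                   if choice_t is not None else np.nan)
        out.append((i, "probswitch", None, choice, correct[blk],
                    "reward" if rewarded else "timeout",
                    True, rewarded, latency, blk, counter[blk]))
    df = pd.DataFrame(out, columns=TRIAL_COLUMNS)
    df.attrs["dropped_trials"] = dropped
    return df


def _infer_correct_sides(rows, n_blocks: int) -> list:
    """Ground-truth side per block: a rewarded trial's chosen port is the
    correct port; blocks without rewards are filled by alternation parity."""
    correct: list = [None] * n_blocks
    for choice, rewarded, blk, _, _ in rows:
        if rewarded and correct[blk] is None:
            correct[blk] = choice
    known = [b for b, c in enumerate(correct) if c is not None]
    if known and len(known) < n_blocks:
        b0 = known[0]
        for b in range(n_blocks):
            if correct[b] is None:
                same_parity = (b - b0) % 2 == 0
                ref = correct[b0]
                correct[b] = ref if same_parity else _other(ref)
    elif not known and n_blocks:
        warnings.warn("no rewarded trials: correct sides unknown", stacklevel=3)
    return correct


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


# ---------------------------------------------------------------------------
# Go/No-Go statistics
# ---------------------------------------------------------------------------

def correct_rate(trials: pd.DataFrame) -> float:
    """(hits + correct rejections) / total trials."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    return float(trials["outcome"].isin(["hit", "cr"]).mean())


def response_latency(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cue-type latency summaries (cue onset to first lick, ms).

    Cue types with no responded trials are absent from the result rather than
    reported as zero.
    """
    with_lat = trials[trials["responded"] & trials["latency_ms"].notna()]
    rows = {}
    for cue, grp in with_lat.groupby("cue", observed=True):
        lat = grp["latency_ms"].astype(float)
        rows[cue] = {
            "n": int(len(lat)),
            "mean": float(lat.mean()),
            "sd": float(lat.std(ddof=1)) if len(lat) > 1 else np.nan,
            "median": float(lat.median()),
            "q25": float(lat.quantile(0.25)),
            "q75": float(lat.quantile(0.75)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Switching-task statistics
# ---------------------------------------------------------------------------

def _reversal_indices(trials: pd.DataFrame) -> list[int]:
    """Positional indices of the last trial of each block but the final one."""
    blocks = trials["block"].to_numpy()
    return [i for i in range(len(blocks) - 1) if blocks[i + 1] != blocks[i]]


def switch_curve(trials: pd.DataFrame, window: int = 5,
                 direction: str | None = None) -> pd.DataFrame:
    """Fraction of left choices aligned on reversals of the rewarded port.

    Position 0 is the last trial of the old block; positive positions are
    trials under the new contingency.  ``direction`` restricts the alignment
    to reversals whose *new* rewarded side is left (``"to_left"``) or right
    (``"to_right"``); by default all reversals contribute.  Returns one row
    per aligned position with the left-choice fraction and the trial count
    behind it.
    """
    revs = _reversal_indices(trials)
    if direction is not None:
        if direction not in ("to_left", "to_right"):
            raise ValueError("direction must be 'to_left', 'to_right' or None")
        new_side = "left" if direction == "to_left" else "right"
        correct = trials["correct_side"].to_numpy()
        revs = [r for r in revs if correct[r + 1] == new_side]
    if not revs:
        raise ValueError("trial table contains no reversal")
    is_left = (trials["choice"] == "left").to_numpy()
    acc: dict[int, list[bool]] = {}
    for r in revs:
        for offset in range(-window, window + 1):
            i = r + offset
            if 0 <= i < len(trials):
                acc.setdefault(offset, []).append(is_left[i])
    rows = [(off, float(np.mean(vals)), len(vals))
            for off, vals in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["position", "frac_left", "n"]) \
             .set_index("position")


def trials_to_switch(trials: pd.DataFrame, max_lag: int | None = None
                     ) -> pd.DataFrame:
    """Mean 1-based lag to the first choice of the newly rewarded port,
    per reversal direction.

    Reversals where the subject never samples the new port within the new
    block (or within *max_lag* trials) are excluded; their count is reported
    via a warning and in ``result.attrs["excluded_reversals"]``.
    """
    revs = _reversal_indices(trials)
    if not revs:
        raise ValueError("trial table contains no reversal")
    choice = trials["choice"].to_numpy()
    correct = trials["correct_side"].to_numpy()
    blocks = trials["block"].to_numpy()
    lags: dict[str, list[int]] = {"right_to_left": [], "left_to_right": []}
    excluded = 0
    for r in revs:
        new_side = correct[r + 1]
        direction = ("right_to_left" if new_side == "left"
                     else "left_to_right")
        lag = None
        j = r + 1
        while j < len(trials) and blocks[j] == blocks[r + 1]:
            k = j - r
            if max_lag is not None and k > max_lag:
                break
            if choice[j] == new_side:
                lag = k
                break
            j += 1
        if lag is None:
            excluded += 1
        else:
            lags[direction].append(lag)
    if excluded:
        warnings.warn(f"{excluded} reversal(s) without a switch to the new "
                      f"port were excluded", stacklevel=2)
    rows = {}
    for direction, vals in lags.items():
        if vals:
            arr = np.asarray(vals, dtype=float)
            rows[direction] = {
                "mean": float(arr.mean()),
                "sem": (float(arr.std(ddof=1) / np.sqrt(len(arr)))
                        if len(arr) > 1 else np.nan),
                "n": len(arr),
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["excluded_reversals"] = excluded
    return out


STAY_PATTERNS = ("rr", "ru", "ur", "uu")  # (t-2, t-1); r rewarded, u not


def stay_probability_by_history(trials: pd.DataFrame) -> pd.DataFrame:
    """Stay fraction conditioned on the reward pattern of two consecutive
    same-port choices.

    For every trial t whose previous two choices (t−2, t−1) went to the same
    port, the pattern is the reward outcome pair of those two trials and the
    trial counts as a "stay" if the choice at t repeats that port.  Patterns
    with no qualifying pairs are absent from the result.
    """
    choice = trials["choice"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    hits: dict[str, list[bool]] = {}
    for t in range(2, len(trials)):
        if choice[t - 2] != choice[t - 1]:
            continue
        pattern = (("r" if rewarded[t - 2] else "u")
                   + ("r" if rewarded[t - 1] else "u"))
        hits.setdefault(pattern, []).append(choice[t] == choice[t - 1])
    rows = {p: {"stay_fraction": float(np.mean(v)), "n": len(v)}
            for p, v in hits.items()}
    return pd.DataFrame.from_dict(rows, orient="index") \
             .reindex([p for p in STAY_PATTERNS if p in rows])


# ---------------------------------------------------------------------------
# Choice-history logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ChoiceHistoryModel:
    """Fitted coefficients (log-odds) of the bias + 5-trial-history model."""

    bias: float
    w_rewarded: np.ndarray    # lag 1..5
    w_unrewarded: np.ndarray  # lag 1..5
    log_likelihood: float
    n: int
    n_back: int = 5

    def coefficients(self) -> np.ndarray:
        return np.concatenate(([self.bias], self.w_rewarded,
                               self.w_unrewarded))

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        """Predicted P(left) for each response trial of *trials* (same
        exclusion of the first ``n_back`` trials as the fit)."""
        y, X = design_matrix(trials, self.n_back)
        logits = X @ self.coefficients()
        return 1.0 / (1.0 + np.exp(-logits))


def design_matrix(trials: pd.DataFrame, n_back: int = 5
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Response vector (left=1) and design matrix [1, r_1..r_k, u_1..u_k].

    The first ``n_back`` trials are excluded from the response set (their
    history is incomplete); trials without a side choice must already have
    been dropped by :func:`trials_from_log`.
    """
    c = np.where(trials["choice"].to_numpy() == "left", 1, -1)
    rew = trials["rewarded"].to_numpy().astype(bool)
    n = len(trials)
    if n <= n_back:
        raise ValueError(f"need more than n_back={n_back} trials, got {n}")
    t_idx = np.arange(n_back, n)
    y = (c[t_idx] == 1).astype(float)
    cols = [np.ones(len(t_idx))]
    for i in range(1, n_back + 1):
        past = c[t_idx - i]
        past_rew = rew[t_idx - i]
        cols.append(np.where(past_rew, past, 0))      # r_i
    for i in range(1, n_back + 1):
        past = c[t_idx - i]
        past_rew = rew[t_idx - i]
        cols.append(np.where(~past_rew, past, 0))     # u_i
    return y, np.column_stack(cols)


class SeparationError(ValueError):
    """Perfect separation: the unpenalized ML fit is unbounded."""


def fit_choice_history_logit(trials: pd.DataFrame, n_back: int = 5,
                             l2_alpha: float | None = None
                             ) -> ChoiceHistoryModel:
    """Maximum-likelihood logistic regression of choice on bias + history.

    Unpenalized fit by iteratively reweighted least squares (IRLS).  If the
    data are separable the fit diverges; pass ``l2_alpha`` for a ridge-
    penalized fit instead.
    """
    y, X = design_matrix(trials, n_back)
    if l2_alpha is not None:
        from sklearn.linear_model import LogisticRegression

        # ridge (L2) penalty is sklearn's default; strength = 1/C
        clf = LogisticRegression(C=1.0 / l2_alpha, fit_intercept=False,
                                 max_iter=1000)
        clf.fit(X, y)
        params = clf.coef_.ravel()
        p = 1.0 / (1.0 + np.exp(-(X @ params)))
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    else:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = model.fit(maxiter=200)
        separated = any("erfect separation" in str(w.message) for w in caught)
        params = np.asarray(res.params)
        if (separated or not np.all(np.isfinite(params))
                or np.max(np.abs(params)) > 25.0):
            raise SeparationError(
                "separation detected (unbounded coefficients); collect more "
                "trials or refit with l2_alpha set")
        llf = float(res.llf)
    return ChoiceHistoryModel(
        bias=float(params[0]),
        w_rewarded=np.asarray(params[1:n_back + 1], dtype=float),
        w_unrewarded=np.asarray(params[n_back + 1:], dtype=float),
        log_likelihood=llf,
        n=len(y),
        n_back=n_back,
    )


def calibration_bins(trials: pd.DataFrame, model: ChoiceHistoryModel,
                     n_bins: int = 50) -> pd.DataFrame:
    """Actual vs predicted left-choice fraction in equal-count bins.

    Trials are sorted by predicted probability and split into ``n_bins``
    equal-count bins; each row reports the bin's mean predicted and empirical
    left fraction.  A constant-prediction model collapses to one bin (with a
    warning).
    """
    p = model.predict(trials)
    y, _ = design_matrix(trials, model.n_back)
    if np.ptp(p) == 0.0:
        warnings.warn("constant predictions: calibration bins collapse to a "
                      "single bin", stacklevel=2)
        return pd.DataFrame({"predicted": [float(p.mean())],
                             "actual": [float(y.mean())],
                             "n": [len(y)]})
    order = np.argsort(p, kind="stable")
    rows = []
    for chunk in np.array_split(order, min(n_bins, len(order))):
        rows.append((float(p[chunk].mean()), float(y[chunk].mean()),
                     len(chunk)))
    return pd.DataFrame(rows, columns=["predicted", "actual", "n"])
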