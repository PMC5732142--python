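# Methods

This note documents the execution model, the parameter choices, the simulated
subjects and the numerical decisions behind `operantsim`, and what the test
suite does and does not establish about real behavioral data.

## Execution model

A session is a finite state machine over TTL lines: integer-valued global
variables, ordered components, and states carrying output actions
(`set_on` / `set_off` / `pulse`), variable assignments, and transition rules.
Exactly one state is active at any virtual instant, and the clock is an
integer count of milliseconds — the resolution at which rig hardware of this
class reports events. Logged timestamps are exact on that grid: the
simulator's logging error is zero, which trivially meets the ±1 ms accuracy
contract such hardware advertises.

The event-driven engine (`operantsim.engine.SessionRunner`) advances directly
between eventful instants; a deliberately naive reference implementation
(`reference_tick_simulator`) advances one millisecond at a time and
re-evaluates every rule. The two share only the data model and the expression
evaluator. Their agreement — event-for-event, on fuzzed random sessions and
traces — is the package's definition of semantic correctness, and is enforced
in the test suite.

Same-instant semantics are fixed as follows:

* Within one millisecond: input edges are applied first, then scheduled pulse
  off-edges, then transitions settle, then the newly entered state's
  assignments and outputs execute. Log presentation order is
  `IN < STATE < OUT` at equal timestamps.
* Rule priority at one instant: `when_count` > `when_var` > `when_pin` >
  `when_time`. Time-out is deliberately last — it is the "if nothing else
  fired" exit. Ties among `when_pin` rules resolve to the lowest channel
  index, then declaration order.
* `when_pin` is edge-triggered on activation (0→1) and an edge can only fire
  a state entered *before* the edge was applied; a channel already high at
  entry does not fire. A per-rule `level_triggered` flag opts into level
  semantics. Edges that fire a transition are consumed once.
* `when_count` keeps a per-state entry counter that never resets within a
  run, and fires on the entry that reaches its threshold *before* the state's
  do-actions run: the visit is logged with zero duration and emits no
  stimuli. This supports the standard trial-counter idiom (end the session
  after N trials) without an extra trial's stimuli.
* Pulse off-edges are scheduled at entry time + duration and outlive the
  state by default (the stimulus, not the state, owns its duration); an
  action-level `cancel_on_exit` flag truncates the pulse at state exit.
  Re-pulsing an already-high channel reschedules the off-edge without
  logging a new on-edge, so on/off events stay balanced per channel.
* `when_time` durations, `when_count` thresholds and pulse durations are
  evaluated once at each state entry (they may reference variables or draw
  random numbers); `when_var` conditions are re-evaluated and must therefore
  be deterministic — the validator rejects random primitives inside them.
* All randomness flows from one generator seeded by the run configuration;
  expression draws and agent draws interleave in a fixed order, so a
  (session, inputs, seed) triple reproduces byte-identical logs.
* Chains of immediately-firing rules are legal (zero-duration visits) up to
  1,000 transitions per instant, beyond which the run aborts with a livelock
  error; a run that never exits ends at the configurable virtual-time cap
  with `exit_reason="time_cap"`.

### Expression language

Variables are integers only — counts, milliseconds, and flags — matching the
arithmetic of the microcontrollers the formalism emulates and keeping
`when_var` conditions decidable. The language is a whitelisted subset of
Python expression syntax: `+ - * / %` (division truncates toward zero, as C
integer division does), comparisons yielding 0/1, short-circuit `and/or/not`,
and two random primitives, `rand_int(lo, hi)` (uniform inclusive) and
`rand_bernoulli_pct(p)` (integer percent, implemented as an exact integer
draw so `p=75` gives exactly 75/100 probability). There are no loops, calls,
floats or attribute access.

## Record levels

The engine always collects everything internally; the record level selects
the view written out. Level 1 keeps nothing (header only), Level 2 keeps the
state stream, Level 3 keeps all input edges on every connected channel —
whether or not they drive state flow — plus output events and transitions.
Level 3 is the default: behavior unfolds on a macro scale against
milliseconds, and comprehensive logging is what the analysis layer needs.
The ASCII log dialect (`#` header lines, tab-separated event lines, explicit
state-exit events so truncated logs stay parseable) is this package's own
documented format; no byte compatibility with any particular rig software is
claimed.

## Tasks

**Go/No-Go** (11 states). A lottery state draws the trial type
(`rand_bernoulli_pct`), routing to a go component (tone pulse; a lick during
cue or response window earns a water pulse) or a no-go component (light
pulse; a lick earns an air puff; withholding is a correct rejection). An
entry counter on the lottery state ends the session after `n_trials`.
Defaults: cue 1,000 ms, response window 1,500 ms, reward valve 50 ms, air
puff 200 ms, ITI 3,000 ms. The cue/window/ITI durations are this package's
documented choices — the task family's published descriptions show the
trial structure, not these numbers — picked to be typical of head-fixed
lick-based discrimination work. The trial-type draw is independent Bernoulli
per trial; no maximum-run constraint is imposed.

**Probabilistic switching** (10 states). The subject pokes the center port
to start a trial and then one side port. One side is correct at a time;
correct choices are rewarded with probability `p_reward` (integer percent,
default 75). A block ends after a uniform-random `rand_int(7, 14)` *rewarded*
trials, so the side reverses only immediately after a rewarded trial. Trials
without reward (wrong port, or an unlucky correct choice) end in a timeout
punishment (default 4,000 ms). Defaults: ITI 3,000 ms, drink period 500 ms,
valve pulses 40 ms per side (settable per side to model unequal reward
sizes; changing them changes only valve-open durations, never the lottery).
The first block's side is a fair coin flip at session start.

*Miss-cap semantics.* To bound reward droughts, if the previous `miss_cap`
(default 2) consecutive trials delivered no reward — for any reason — the
current trial's availability lottery is forced to "available". This is the
weakest intervention that guarantees the stated bound for a subject on the
correct port; for a subject on the wrong port no intervention can guarantee
a reward, and the forced availability simply persists until the correct port
is sampled. The cap distorts the marginal reward rate upward (≈76.6%
observed for an oracle chooser at 75%), so `enable_miss_cap=False` is
provided for unbiased estimation of the lottery itself. Whether the cap
should count wrong-port losses is genuinely ambiguous in the task family's
descriptions; counting all unrewarded trials is the simpler reading and the
flag covers the alternative analysis.

Ground truth for analysis is reconstructed from the Level ≥ 2 state stream
alone: block boundaries are `switch_block` entries, and a block's correct
side is the chosen side of any rewarded trial in it (a reward implies the
correct port); reward-free blocks are filled by alternation parity.

## Simulated subjects

Agents observe the events of each virtual instant (output edges and state
entries) and schedule future input edges; the engine enforces causality by
clamping returned edges to at least the next millisecond.

* **Go/No-Go agent** — licks after the go cue with probability `p_hit` and
  after the no-go cue with `p_fa`. First-lick latency is truncated normal
  (defaults mean 300 ms, sd 100 ms, floor 50 ms) — the family is this
  package's choice; published latency histograms for the task show shape but
  not parameters. A decision emits a bout of 5 licks at 8 Hz (30 ms
  contacts); the rate is validated against the ~15 Hz murine ceiling, and
  inter-lick onsets in simulated logs respect 1000/15 ms. A
  `learning_trajectory` fixture (exponential approach from
  p_hit=0.8/p_fa=0.4 toward 0.95/0.05) supports across-session learning
  curves; it is a fixture, not a model of acquisition.
* **Choice-history agent** — chooses left with probability
  σ(bias + Σᵢ βᵢᴿ r₋ᵢ + Σᵢ βᵢᵁ u₋ᵢ) over its own previous five trials, with
  the signed coding described in the analysis section. Outcomes are observed
  from valve pulses. Saturating the lag-1 weights at ±10 log-odds yields the
  win-stay/lose-shift preset (a finite stand-in for ±∞; the per-decision
  deviation probability is 4.5×10⁻⁵).
* **Oracle agent** — always chooses the currently rewarded port, reading the
  scheduler's `side` variable through a read-only engine view. It exists to
  calibrate estimators (reward fraction, block statistics) free of choice
  noise; no claim is made that any agent parameterization is "the" mouse.

What the agents do **not** capture: consummatory licking, motivation and
satiety drifts, post-error slowing, side-specific motor costs, or any
within-session learning. Passing tests therefore certify the engine,
scheduler and estimators — not conclusions about animals.

## Analyses

Trial tables carry one row per completed trial (truncated trailing trials
dropped; choice trials without a side response excluded and counted in
`attrs["dropped_trials"]`). Correct rate is (hits + correct rejections) /
trials. Latency is cue onset to first lick, computed only for responded
trials.

Reversal alignment: position 0 is the last trial of the old block — the
rewarded trial that triggered the switch — so position +1 is the first trial
under the new contingency and `trials_to_switch` (the 1-based index of the
first new-port choice) is always ≥ 1. Reversals never followed within the
new block are excluded with a warning count.

The choice-history regression codes choice cₜ ∈ {+1 left, −1 right},
rᵢ = cₜ₋ᵢ if trial t−i was rewarded else 0, uᵢ the complement — the standard
coding for this task family. The fit is unpenalized maximum likelihood via
IRLS (statsmodels GLM/Binomial); the first `n_back` trials are excluded from
the response set. Perfect separation (e.g. near-deterministic choice
sequences) is detected and raised with advice to use the optional ridge
(`l2_alpha`) fit. Calibration sorts trials by predicted probability into
equal-count bins (default 50) and compares mean predicted with empirical
left fraction; a constant-prediction model collapses to one bin with a
warning. Logs from multiple sessions can be analyzed separately (one table
per log) or pooled by concatenating tables; the CLI `analyze` command pools
and tags rows with a session index.

## Problem sizes and seeds

The scheduler statistics are computed on 20,000-trial oracle runs
(~1,450 completed blocks), the certainty variant on 5,000 trials, the
Go/No-Go correct rate on 500 trials, and regression recovery on 20,000
trials per condition (all 11 coefficients recovered within ±0.1 log-odds;
a history-blind agent recovers within ±0.05 of zero). Calibration of a
well-specified model uses 50,000 trials and 50 bins (per-bin agreement
within 0.05). The suite's broader recovery property (random weight vectors
in [−1.5, 1.5]) runs 5 vectors × 5,000 trials with the same median-error
bound — the per-coefficient standard error at that size (≈0.04) leaves wide
margin. Engine/reference-simulator equivalence is fuzzed over 100 random
sessions with 400 ms horizons. All tests and the acceptance script are
seeded; stochastic assertions use 3-standard-deviation (binomial) or
equivalent bounds.

## Known limitations

* No real-time execution or serial communication with physical boards;
  sub-millisecond hardware timing properties are out of scope by design.
* Nested components, per-state local variables and floating-point variables
  are not supported.
* The miss-cap bound is a guarantee about reward *availability*, not
  delivery, for subjects that sample the wrong port (see above).
* Whether entry counters should reset when a component is re-entered is
  unspecified in the formalism's public descriptions; this implementation
  never resets them within a run.
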