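# operantsim

Virtual-time state-machine control of operant-conditioning tasks, with
simulated subjects and choice-behavior analyses.

Behavioral rigs for rodent operant conditioning are commonly programmed in a
*State Notation* formalism: a task is a finite state machine over binary TTL
input lines (lick and poke sensors) and output lines (tones, lights, valves,
air puffs), where each State bundles output actions (*do*-functions), exit
conditions (*when*-functions: entry count, input edge, time-out, variable
test) and destinations. `operantsim` re-creates that execution model as a
deterministic discrete-event simulator on an integer-millisecond virtual
clock, so task logic, logging and analysis pipelines can be developed,
validated and stress-tested entirely in software — with simulated mice
closing the loop — before anything touches a rig. It is aimed at behavioral
neuroscientists and tool builders who want reproducible, seed-exact dry runs
of task schedules and their analyses.

The package provides:

* **task model + validator** — the State/Component/Session hierarchy, a
  sandboxed integer expression language for global variables
  (`rand_int`, `rand_bernoulli_pct` for reward lotteries), and static checks
  including the 20-state memory budget of the low-end microcontroller
  profile (`uno`);
* **engine** — an event-driven executor with fixed same-instant semantics
  (priority `when_count` > `when_var` > `when_pin` > `when_time`), plus an
  independent 1-ms-tick reference simulator used as a semantics oracle;
* **three-level event logging** — Level 1 none, Level 2 state transitions
  only, Level 3 everything including every edge on every connected input;
  an ASCII log dialect and tabular export;
* **tasks** — parametrized builders for a Go/No-Go discrimination task and a
  spatial two-alternative probabilistic-switching task (one port rewarded
  75% at a time, blocks of 7–14 rewarded trials, reversal only after a
  rewarded trial, at most 2 consecutive unrewarded trials);
* **agents** — simulated subjects: a cue-triggered licker with hit /
  false-alarm probabilities and truncated-normal latencies, a logistic
  choice-history chooser, a pure win-stay/lose-shift preset, and a
  ground-truth oracle chooser;
* **analysis** — trial segmentation from logs, correct rate, lick latencies,
  reversal-aligned choice curves, trials-to-switch, conditional stay
  probabilities, and the choice-history logistic regression

  $$\log\frac{P(\text{left}_t)}{P(\text{right}_t)} = \beta_0
    + \sum_{i=1}^{5}\beta^{R}_i\,r_{t-i} + \sum_{i=1}^{5}\beta^{U}_i\,u_{t-i},$$

  where $r_{t-i}$ is the signed past choice (+1 left, −1 right) if that trial
  was rewarded and 0 otherwise, and $u_{t-i}$ the complement for unrewarded
  trials, with calibration binning of predicted vs actual choice fractions.

## Worked example

```python
from operantsim import EngineConfig, build_prob_switch, trials_from_log
from operantsim.agents import wsls_agent, simulate_session
from operantsim.analysis import stay_probability_by_history, trials_to_switch
from operantsim.tasks import ProbSwitchParams

session = build_prob_switch(ProbSwitchParams(n_trials=600, p_reward=100))
result = simulate_session(session, wsls_agent(), EngineConfig(seed=11))
trials = trials_from_log(result.log, session)
print(trials_to_switch(trials))
print(stay_probability_by_history(trials))
```

prints

```
               mean  sem   n
right_to_left   2.0  0.0  27
left_to_right   2.0  0.0  27
    stay_fraction    n
rr            1.0  490
ru            0.0   54
```

A pure win-stay/lose-shift subject at 100% reward certainty follows every
reversal with a lag of exactly 2 trials: the first post-reversal trial stays
on the old (just-rewarded) port, the second shifts. Its stay fraction is 1
after two rewarded same-port choices (`rr`, the within-block steady state)
and 0 when the second of the pair went unrewarded (`ru`, the post-reversal
loss); patterns beginning with a loss (`ur`, `uu`) never occur because a
lose-shift subject does not make two consecutive same-port choices after
losing.
The same pipeline applied to the stochastic choice-history agent recovers
the generating bias and all ten history weights to within ±0.1 log-odds at
20,000 trials (see `tests/test_acceptance.py`).

The command-line interface wraps the same functionality:

```sh
operantsim build probswitch -p n_trials=600 -p p_reward=100 -o switch.task.yaml
operantsim validate switch.task.yaml
operantsim simulate switch.task.yaml --agent wsls --seed 11 --out-dir logs/
operantsim analyze logs/session_000.aclog --task-file switch.task.yaml -r trials.tsv
```

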