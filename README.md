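# beliefreplay

Prioritised replay in belief-state MDPs: a simulation library for studying
how offline value backups ("replay"), scheduled by exploratory
Gain × Need, can plan *directed exploration* under uncertainty.

## The problem and the model

Animals and artificial agents alike face environments they only partially
know — an option with an uncertain payoff, a corridor that may or may not be
blocked.  Classical prioritised-replay theory schedules each offline Bellman
backup by its **expected value of backup**,
`EVB(s_k, a_k) = Need(s_k) × Gain(s_k, a_k)`, where *Gain* is the local
policy improvement the backup buys and *Need* is the discounted expected
occupancy of the updated state.  That theory assumes the environment is
fully known, so the replay it prescribes is purely exploitative.

`beliefreplay` implements the belief-state generalisation.  The agent's state
becomes a belief state `b = {s, p(P)}` — its physical location plus a
conjugate Beta belief over each unknown Bernoulli quantity — and replay
schedules backups over belief states:

    EVB(b_k, a_k) = Σ_b  Need(b) · Σ_a [π_new(a|b) − π_old(a|b)] Q_new(b, a)

The outer sum expresses generalisation: one physical action value is shared
by many belief states, and a single backup benefits all of them.  Because
backups run through the belief transition model — attempting an uncertain
barrier forks into a resolved-open and a resolved-closed future — replay
automatically prices the *information* an exploratory action yields, and
directed exploration emerges from the same machinery that otherwise yields
exploitative replay.  A far-sighted **sequence replay** mechanism evaluates
whole chains of backups at once, which is what lets bad news (a hoped-for
shortcut turns out closed) propagate deeply instead of stalling.

Two testbeds are built in:

* **Bayes-adaptive bandit trees** — finite-horizon belief trees for Bernoulli
  bandits, with exact Bayes-optimal (backward induction) and
  certainty-equivalent reference values;
* **a Tolman-style detour maze** — a gridworld with directional barriers,
  an online Q-learning + forgetting + replay agent, and a Monte-Carlo
  estimator of exploratory Need over the discretised belief space.

## Worked example

The canonical demonstration is a two-arm bandit whose first arm has an
unknown payoff (flat `Beta(1,1)` belief, mean 0.50) and whose second arm is
known to pay 0.51 — the known arm looks better, but only just, and the
unknown arm carries information.  Replay in the horizon-3 belief tree:

```bash
$ belief-replay run fig2_bandit_h3 --seed 0
{
  "n_updates": 5,
  "root_greedy_value": 1.7846611111111108,
  "evaluated_policy_value": 1.7846611111111108,
  "bo_root_value": 1.883258333333333,
  "ce_root_value": 1.6999999999999997,
  "root_greedy_arm": 2
}
```

The bout executes exactly **5** prioritised backups before the best
remaining EVB falls below the threshold ξ.  Those five updates lift the
root's value from the certainty-equivalent floor (`ce_root_value` 1.70 —
what a planner that collapses uncertainty to its mean believes) most of the
way to the Bayes-optimal value (`bo_root_value` 1.88 — full dynamic
programming over the belief tree); driving ξ → 0 closes the remaining gap to
below 1e-6.  The difference BO − CE is the value of information, and it is
strictly positive whenever the prior is genuinely uncertain.

The maze counterpart plants a `Beta(7,2)` belief (probably open) on a
barrier that would shortcut the agent's learned route:

```bash
$ belief-replay run fig5_exploratory --seed 0
{
  "n_updates_exploratory": 5,
  "start_greedy_action": 0,
  "start_points_to_barrier": true,
  "n_updates_discovery": 1,
  "n_inflated_chain_states": 4,
  ...
}
```

Replay executes a reverse chain of five backups from the barrier down to the
start, and the new model-free policy at the start points up the uncertain
corridor (`start_greedy_action: 0` = UP): exploration has been compiled into
the behavioural policy offline.  If the barrier is then discovered closed,
single-action replay performs one myopic update and leaves four corridor
states carrying the obsolete exploration bonus (`n_inflated_chain_states`);
re-running with sequence replay (`belief-replay run fig6_sequence`) executes
one corrective reverse sequence and restores the whole chain.

Other built-in scenarios: `fig1_bandit_h2` (exploratory vs certainty-
equivalent Gain), `fig3_baseline_tolman` (a certainty-assuming replay agent
never discovers an opened shortcut), `fig4_single_barrier_tree`,
`fig7_corridor` (replay inside a doubly-blocked corridor, spanning belief
states the agent has never visited), `fig7d_tmaze` (rest replay confined to
a cued arm), `supp_two_unknown_arms` (reverse-replay bias),
`supp_prior_sweep`.  `belief-replay sweep --grid grid.yaml` runs ξ/horizon/β
sweeps.  Every scenario is fully determined by its config and `--seed`, and
writes a manifest + tidy CSV tables with `--out`.

## Layout

```
src/beliefreplay/
  beliefs.py        Beta beliefs, belief states, belief-space discretisation
  bandit.py         belief trees, backward induction, CE references
  maze.py           gridworld, barriers, transition models, value iteration
  agent.py          Q-learning, softmax, forgetting, memory buffer
  replay_md.py      known-environment Gain x Need replay (the baseline)
  replay_belief.py  belief-space backups, exploratory Gain/Need, EVB loops
  sequences.py      forward/reverse sequence generation and far-sighted EVB
  experiments.py    scenario definitions and sweeps
  cli.py            `belief-replay` command line
docs/methods.md     model assumptions, estimators, parameter defaults
```
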