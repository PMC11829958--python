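# Methods

`beliefreplay` simulates a normative account of hippocampal replay as
prioritised offline planning under uncertainty.  An agent that is ignorant
about parts of its environment — the payoff of a bandit arm, the presence of
a barrier in a maze — is modelled as acting in a *belief MDP*: each state
`b` pairs the physical situation `s` (if any) with a probability distribution
over the unknown quantities.  Offline replay schedules Bellman backups over
belief states in the order of their *expected value of backup*,

    EVB(b_k, a_k) = sum_b Need(b) * Gain(b),

executing backups while the best EVB exceeds an opportunity-cost threshold
`xi`.  `Gain(b) = sum_a [pi_new(a|b) - pi_old(a|b)] Q_new(b, a)` is the local
policy improvement a backup buys at belief state `b`; `Need(b)` is the
discounted expected future occupancy of `b` under the pre-update policy.
Because replay runs over beliefs rather than physical states, the scheme
values *information*: a backup at an action with uncertain consequences
carries the worth of resolving that uncertainty and exploiting the answer
later, so directed exploration emerges from replay rather than from ad-hoc
bonuses.

## Beliefs

Unknown Bernoulli parameters carry conjugate `Beta(alpha, beta)` beliefs;
one observation adds one pseudo-count.  Certainty is a distinct marker
(`KnownPayoff`, `ResolvedOpen/Closed`), never a degenerate Beta, which keeps
belief equality exact (all in-scope updates add integers) and makes contract
violations (updating something already known) detectable.  Direct barrier
observations resolve the belief *hard* — the transition probability becomes 0
or 1 with no residual uncertainty — while imagined outcomes inside bandit
planning trees use the soft conjugate update.  This asymmetry mirrors the two
testbeds: a maze barrier is either present or not and one attempt settles it;
an arm's payoff probability is never settled by one pull.

## Bandit belief trees

For a Bernoulli bandit the belief tree is expanded exactly to a horizon `h`:
pulling an unresolved arm forks into a success child (probability = the
predictive mean, reward 1) and a failure child; pulling a known arm yields
one child carrying its expected reward.  Leaves are initialised to their
certainty-equivalent long-run values `max_k E[mu_k]/(1-gamma)`; internal
action values start at 0 (they are genuinely unknown to the agent).  Nodes
with identical beliefs at different depths are *not* merged; each node is
reached along exactly one path, so Need is computed exactly as the
gamma-discounted path probability under the softmax behavioural policy, and
the effect of a backup is local to its node.  Backward induction over the
same tree defines the Bayes-optimal (BO) reference value; collapsing each
unresolved arm to its mean before induction defines the certainty-equivalent
(CE) reference.  Replay with `xi -> 0` provably terminates (leaves are fixed;
each node changes finitely often) and empirically reaches the BO root value
and BO greedy-policy value to well below 1e-6.

Free parameters for the canonical example (one `Beta(1,1)` arm versus a known
0.51 arm) are `gamma = 0.7`, `beta = 1`, `xi = 0.0165`, horizon 3.  The
example bout is defined by its characteristic five-update length, and
`gamma` and `xi` are fixed jointly by that property: the greedy EVB sequence
admits a "stop after exactly five" threshold only for `gamma <~ 0.76` under
the unmerged-tree convention, and `xi` is the midpoint of the admissible
interval at `gamma = 0.7`.  Under these conventions the five-update bout
propagates exploratory value through the known-arm spine of the tree; the
root's preference for the unknown arm appears as `xi -> 0`.

## Maze belief space

The maze discretises belief space to `disc_h(B)`: per uncertain barrier the
belief is one of {prior, resolved-open, resolved-closed}, and only belief
states *jointly reachable* within the planning horizon `h` from the agent's
current belief state are represented (a cell that can only be entered by
crossing a barrier is never paired with that barrier's unresolved prior).
Action values `Q_MB(b, a)` are stored per discretised belief state and
initialised lazily from the model-free table at the physical state, which
also supplies values beyond the horizon.

A backup *generalises*: physical action values are shared across belief
states, so one candidate updates every discretised belief state with the same
physical state and the same belief about the attempted barrier — each with
its own one-step backup through its own children — and its EVB sums
Need-weighted Gain over that affected set.  This is the operational form of
the outer sum over belief space in the prioritisation, and it is what lets a
single replay update benefit the many beliefs under which a barrier can be
revisited.

After a bout, backups executed at the agent's *current* belief configuration
are written through to the model-free table ("the new model-free policy");
backups at imagined posterior beliefs stay model-based only.

## Monte-Carlo Need

Need over `disc_h(B)` is estimated from `N` rollouts (default 1000; seeded
per refresh from one master seed) that start at the current belief state,
follow the softmax policy over the current `Q_MB`, and resolve sampled
barrier attempts hard.  A trajectory runs while `gamma^d > eps`
(`eps = 1e-5`), recording the first-hit step `K_i(b)` of every discretised
belief state.  The estimate combines the within-horizon term `gamma^{K_i(b)}`
with a certainty-equivalent tail that assumes stationary dynamics beyond the
first hit.  The default tail is the renewal form

    Need(b) ~= mean_i gamma^{K_i(b)} * [(I - gamma T_c)^{-1}]_(s, s),

with `T_c` the policy-weighted expected transition operator of `b`'s belief
configuration; by the strong Markov property this is *exactly unbiased* for
the discounted successor representation once no uncertainty remains, which is
the property the estimator is meant to have (it matches the resolvent closed
form within Monte-Carlo error on barrier-free mazes).  An alternative tail
that adds the unconditional matrix-power series indexed from the agent's
state, `[sum_{j>K_i} (gamma T_c)^j]_(s_rho, s)`, is available as
`tail="series"`; it is biased upward whenever first-hit times correlate with
later occupancy (a two-state example makes the bias ~5%), so it is not the
default.  Unhit trajectories contribute zero.  Need is refreshed after every
executed update by default (`need_refresh="bout"` freezes it per bout).

## Sequence replay

A sequence event updates an ordered chain of (belief state, action) pairs
within one replay iteration on a shared scratch copy, so for *reverse*
events each later element's backup consumes the already-updated value of its
child — one event can carry good or bad news many steps.  The far-sighted
EVB of a sequence is the sum of its per-element EVBs, each evaluated at the
intermediate value state after all earlier elements (this resolves the
bookkeeping that the fractional-update notation leaves open, for forward
sequences too).  Generation grows chains from all single-action candidates
under three constraints: physical states never repeat, an extension survives
only if the extended EVB clears `xi`, and chains stay inside `disc_h(B)`.
Reverse chains step backwards through the forward transition model (the same
uncertainty is assigned to reverse transitions; no inverse model is
learned).  A beam cap (default 64 per length) bounds the combinatorics in
the maze; bandit trees are searched exhaustively.

In maze scenarios sequence events are additionally *anchored*: the far end of
the replayed trajectory (the first executed element of a reverse event, the
last element of a forward one) must attempt a barrier or enter the goal, and
an anchored event clearing `xi` is executed in preference to lone
single-action updates, with longer chains preferred among equal-EVB events.
This implements the termination convention that maze sequences link critical
decision points — a chain runs from the barrier to the intersection by the
start — and it is load-bearing: under a pure max-EVB competition the
discovery bout's winner is always the myopic single update that raises the
retreat action toward the still-inflated neighbour (its EVB exceeds any
corrective chain's by an order of magnitude for every `gamma`, `beta`
tested), which reproduces the single-action pathology but would also block
the sequence correction.  Anchoring is a property of the maze scenarios;
bandit-tree replay keeps free competition between singles and sequences.
Maximal length defaults to the start-to-barrier action chain (5 in the
built-in maze) and to the horizon in bandit protocols.

## Maze environment and online learner

The built-in detour maze is a 5 x 6 grid: three vertical corridors join a
bottom row (start at its centre) and a top row leading to the goal, with
routes of 6, 8 and 10 moves.  Barriers sit at the exit of the shortest
(central) corridor, the exit of the left corridor, and optionally the
central corridor's entrance (bidirectional, for the blocked-corridor
scenario); one-directional barriers block and teach only from below.
Entering the goal pays `goal_reward = 1` and teleports to the start with no
discount break (an absorbing convention is available), matching continual
sessions with repeated goal visits.  Exact grid dimensions are a design
choice; the corridor-length ordering and barrier placement are the contract.

The online baseline is a tabular Q-learner (`alpha = 0.6`) with softmax
control (`beta = 20` online) over each cell's *legal* moves, exponential
forgetting of Q toward its initialisation (`phi = 5e-4` per move) to sustain
continual replay, a one-slot-per-(s, a) memory buffer, and a transition model
that starts barrier-free and is rewritten to the observed one-hot row on
every barrier attempt.  After every move it replays memory backups by the
known-environment Gain x Need priority until EVB < `xi = 0.02`.  The
before/after-change session runs 2000 + 2000 moves; its first phase closes
only the central barrier (the left detour stays open), which a uniform
initial policy reliably solves within the session (with both detours closed,
roughly a quarter of runs never find the goal in 2000 moves).

## What the scenarios do and do not show

The scenarios regenerate the model's qualitative behaviours at desk scale:
the exploratory-versus-exploitative Gain contrast, convergence of prioritised
replay to dynamic programming, the strict value of information, baseline
blindness to an opened shortcut, uncertainty-gated exploration (a `Beta(7,2)`
prior on the barrier redirects the start policy; `Beta(2,20)` does not), deep
corrective propagation by reverse sequences, rest replay confined to a cued
T-maze arm, and the reverse-over-forward sequence bias.  They are synthetic
and parameterised by the package's canonical defaults, so passing them shows internal
consistency of the model under these study conditions, not quantitative fit
to neural or behavioural recordings; inferential statistics over replicate
counts are out of scope.

Problem sizes used by the shipped checks: horizon-2..4 trees (up to 121
nodes), 50-200 random priors per property, 10^4 Need rollouts, 2000-move
phases with 3 repeats, 20 protocol seeds for direction statistics.  Every
run is fully determined by (config, seed); Monte-Carlo components consume
per-bout child seeds of one master seed.

## Numerical choices

Value iteration stops at a max Q change of 1e-5 (synchronous sweeps).
Softmax is max-stabilised; `beta = 0` is uniform.  EVB ties break toward the
event seen first in a deterministic (state, belief, action) order, with a
single action preferred over an equal-EVB sequence (fewer updates for equal
benefit) except among anchored maze events, where the longer chain wins.
Greedy readouts break ties by lowest action index (up, down, left, right).
Replay loops carry a hard update cap as a safety net; it is never reached at
the shipped thresholds.
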