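"""Conjugate Bernoulli-Beta beliefs and the finite discretisation of belief space.

The agent's epistemic state about a single unknown Bernoulli parameter -- an arm's
payoff probability, or the probability that a barrier is passable ("open") -- is a
Beta density ``Beta(alpha, beta)``.  Certainty is represented explicitly: a known
arm payoff is :class:`KnownPayoff` and a barrier observed directly is
:class:`Resolved` (open or closed), never a degenerate Beta.

A *belief state* pairs the agent's physical situation with one belief entry per
unknown quantity: :class:`BanditBeliefState` (no physical state) and
:class:`MazeBeliefState` (grid cell ``s`` plus per-barrier entries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union


@dataclass(frozen=True)
class BetaBelief:
    """Beta(alpha, beta) belief over a Bernoulli success probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("Beta pseudo-counts must be positive")

    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def update(self, success: bool) -> "BetaBelief":
        """Conjugate posterior after one Bernoulli observation."""
        if success:
            return BetaBelief(self.alpha + 1, self.beta)
        return BetaBelief(self.alpha, self.beta + 1)


@dataclass(frozen=True)
class KnownPayoff:
    """An arm whose payoff probability mu is known with certainty."""

    mu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("payoff probability must lie in [0, 1]")


@dataclass(frozen=True)
class Resolved:
    """A barrier whose presence has been observed directly (no residual uncertainty)."""

    open: bool


RESOLVED_OPEN = Resolved(True)
RESOLVED_CLOSED = Resolved(False)

BeliefEntry = Union[BetaBelief, KnownPayoff, Resolved]


def update_belief(belief: BetaBelief, outcome: str | bool) -> BetaBelief:
    """One conjugate Bayesian update of an unresolved belief.

    ``outcome`` may be ``"success"``/``"failure"`` or a bool.  Updating a
    :class:`Resolved` or :class:`KnownPayoff` entry is a contract violation:
    there is nothing left to learn.
    """
    if not isinstance(belief, BetaBelief):
        raise TypeError(f"cannot update a resolved/known belief: {belief!r}")
    if isinstance(outcome, str):
        if outcome not in ("success", "failure"):
            raise ValueError(f"unknown outcome {outcome!r}")
        outcome = outcome == "success"
    return belief.update(bool(outcome))


def predictive_probability(entry: BeliefEntry) -> float:
    """Predictive (mean) success probability of a belief entry."""
    if isinstance(entry, BetaBelief):
        return entry.mean()
    if isinstance(entry, KnownPayoff):
        return entry.mu
    if isinstance(entry, Resolved):
        return 1.0 if entry.open else 0.0
    raise TypeError(f"not a belief entry: {entry!r}")


@dataclass(frozen=True)
class BanditBeliefState:
    """Belief state of a Bernoulli bandit: one entry per arm."""

    arms: tuple[BeliefEntry, ...]

    def __post_init__(self) -> None:
        if len(self.arms) < 1:
            raise ValueError("a bandit needs at least one arm")

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def expected_payoffs(self) -> tuple[float, ...]:
        return tuple(predictive_probability(a) for a in self.arms)

    def pull(self, k: int, success: bool) -> "BanditBeliefState":
        """Posterior belief state after observing one pull of arm ``k``."""
        arm = self.arms[k]
        if isinstance(arm, KnownPayoff):
            return self  # no new information
        arms = list(self.arms)
        arms[k] = update_belief(arm, success)
        return BanditBeliefState(tuple(arms))


@dataclass(frozen=True)
class MazeBeliefState:
    """Joint physical/epistemic state in a maze: cell ``s`` plus per-barrier beliefs."""

    s: int
    barrier_beliefs: tuple[BeliefEntry, ...]

    def with_state(self, s: int) -> "MazeBeliefState":
        return MazeBeliefState(s, self.barrier_beliefs)

    def resolve(self, barrier_index: int, open: bool) -> "MazeBeliefState":
        entries = list(self.barrier_beliefs)
        entries[barrier_index] = RESOLVED_OPEN if open else RESOLVED_CLOSED
        return MazeBeliefState(self.s, tuple(entries))


def _entry_key(entry: BeliefEntry) -> tuple:
    if isinstance(entry, BetaBelief):
        return ("beta", entry.alpha, entry.beta)
    if isinstance(entry, KnownPayoff):
        return ("known", entry.mu)
    return ("resolved", entry.open)


def belief_key(state: BanditBeliefState | MazeBeliefState) -> tuple:
    """Canonical hashable identifier: equal beliefs map to equal keys.

    All in-scope updates add integer pseudo-counts, so equality on the raw
    (alpha, beta) is exact and no epsilon-bucketing is required.
    """
    if isinstance(state, BanditBeliefState):
        return ("bandit",) + tuple(_entry_key(a) for a in state.arms)
    if isinstance(state, MazeBeliefState):
        return ("maze", state.s) + tuple(_entry_key(e) for e in state.barrier_beliefs)
    raise TypeError(f"not a belief state: {state!r}")


def barrier_combinations(
    entries: Iterable[BeliefEntry],
) -> list[tuple[BeliefEntry, ...]]:
    """All belief-entry combinations used by the finite discretisation.

    Each unresolved (Beta) entry contributes {prior, resolved-open,
    resolved-closed}; resolved entries stay fixed.
    """
    combos: list[tuple[BeliefEntry, ...]] = [()]
    for e in entries:
        options = (e, RESOLVED_OPEN, RESOLVED_CLOSED) if isinstance(e, BetaBelief) else (e,)
        combos = [c + (o,) for c in combos for o in options]
    return combos


def discretize_reachable(root: MazeBeliefState, horizon: int, spec,
                         joint: bool = True) -> set[MazeBeliefState]:
    """``disc_h(B)``: the finite, horizon-limited discretisation of belief space.

    Per uncertain barrier the belief component is one of {prior,
    resolved-open, resolved-closed}.  With ``joint=True`` (default) the set
    contains exactly the belief states reachable from the root within
    ``horizon`` moves of the belief transition model (a crossbar cell paired
    with an unresolved barrier belief, say, is excluded: reaching it resolves
    the belief).  ``joint=False`` gives the looser cross product of belief
    combinations with physically reachable states.  The root is always
    contained.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    from .maze import ACTIONS, reachable_states  # local import to avoid a cycle

    if not joint:
        states = reachable_states(spec, root, horizon)
        combos = barrier_combinations(root.barrier_beliefs)
        disc = {MazeBeliefState(s, c) for s in states for c in combos}
        disc.add(root)
        return disc

    from .replay_belief import children_of

    frontier = {root}
    seen = {root}
    for _ in range(horizon):
        nxt = set()
        for b in frontier:
            for a in ACTIONS:
                for child, p, _ in children_of(spec, b, a):
                    if p > 0 and child not in seen:
                        seen.add(child)
                        nxt.add(child)
        frontier = nxt
        if not frontier:
            break
    return seen


# -- plain-text (JSON-compatible) serialisation -------------------------------


def entry_to_dict(entry: BeliefEntry) -> dict:
    if isinstance(entry, BetaBelief):
        return {"kind": "beta", "a": entry.alpha, "b": entry.beta}
    if isinstance(entry, KnownPayoff):
        return {"kind": "known", "mu": entry.mu}
    return {"kind": "resolved", "open": entry.open}


def entry_from_dict(d: dict) -> BeliefEntry:
    kind = d["kind"]
    if kind == "beta":
        return BetaBelief(d["a"], d["b"])
    if kind == "known":
        return KnownPayoff(d["mu"])
    if kind == "resolved":
        return RESOLVED_OPEN if d["open"] else RESOLVED_CLOSED
    raise ValueError(f"unknown belief entry kind {kind!r}")


def state_to_dict(state: BanditBeliefState | MazeBeliefState) -> dict:
    if isinstance(state, BanditBeliefState):
        return {"s": None, "beliefs": [entry_to_dict(a) for a in state.arms]}
    return {"s": state.s, "beliefs": [entry_to_dict(e) for e in state.barrier_beliefs]}


def state_from_dict(d: dict) -> BanditBeliefState | MazeBeliefState:
    entries = tuple(entry_from_dict(e) for e in d["beliefs"])
    if d.get("s") is None:
        return BanditBeliefState(entries)
    return MazeBeliefState(int(d["s"]), entries)
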