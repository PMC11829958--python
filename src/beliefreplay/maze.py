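"""Tolman-style gridworld MDPs with directional barriers.

Cells are indexed row-major with row 0 at the *bottom*, so ``UP`` increases the
row.  A barrier sits on the edge between a designated approach cell and its
neighbour in a given direction.  A one-directional barrier blocks (and can be
learnt about) only when attempted from the designated side; the reverse crossing
is free.  A bidirectional barrier blocks and teaches from both sides.

The built-in :func:`tolman_maze` fixture has three corridors of distinct lengths
(6 / 8 / 10 moves start-to-goal) merging onto a common top row, an uncertain
"top" barrier at the exit of the shortest (central) corridor, a second barrier
on the middle-length (left) corridor, and an optional bidirectional "bottom"
barrier at the central corridor's entrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .beliefs import MazeBeliefState, Resolved, predictive_probability


class Action(IntEnum):
    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3


ACTIONS = tuple(Action)
_DELTAS = {Action.UP: (1, 0), Action.DOWN: (-1, 0), Action.LEFT: (0, -1), Action.RIGHT: (0, 1)}
_OPPOSITE = {Action.UP: Action.DOWN, Action.DOWN: Action.UP,
             Action.LEFT: Action.RIGHT, Action.RIGHT: Action.LEFT}


@dataclass(frozen=True)
class Barrier:
    """A (possibly directional) barrier on the edge (cell, cell + direction)."""

    cell: int
    direction: Action
    bidirectional: bool = False
    truly_open: bool = False


@dataclass(frozen=True)
class MazeSpec:
    width: int
    height: int
    start: int
    goal: int | None
    walls: frozenset = field(default_factory=frozenset)      # normalised (lo, hi) cell pairs
    obstacles: frozenset = field(default_factory=frozenset)  # solid cells
    barriers: tuple[Barrier, ...] = ()
    goal_reward: float = 1.0
    reset: str = "start"  # episode convention: "start" (teleport) or "absorb"

    def __post_init__(self) -> None:
        if self.start == self.goal:
            raise ValueError("start and goal must differ")
        if self.reset not in ("start", "absorb"):
            raise ValueError("reset must be 'start' or 'absorb'")
        for b in self.barriers:
            if self.neighbor(b.cell, b.direction) is None:
                raise ValueError(f"barrier edge leaves the grid: {b}")

    @property
    def n_states(self) -> int:
        return self.width * self.height

    def cell(self, row: int, col: int) -> int:
        return row * self.width + col

    def rowcol(self, s: int) -> tuple[int, int]:
        return divmod(s, self.width)

    def neighbor(self, s: int, a: Action) -> int | None:
        r, c = self.rowcol(s)
        dr, dc = _DELTAS[Action(a)]
        r2, c2 = r + dr, c + dc
        if not (0 <= r2 < self.height and 0 <= c2 < self.width):
            return None
        return self.cell(r2, c2)

    def wall_between(self, s: int, t: int) -> bool:
        return (min(s, t), max(s, t)) in self.walls

    def barrier_on(self, s: int, a: Action) -> tuple[int, bool] | None:
        """Barrier index on the edge traversed by (s, a), and whether this
        approach is from a blocking/teaching side."""
        t = self.neighbor(s, a)
        if t is None:
            return None
        for i, b in enumerate(self.barriers):
            if b.cell == s and b.direction == a:
                return i, True
            if self.neighbor(b.cell, b.direction) == s and _OPPOSITE[b.direction] == Action(a):
                return i, bool(b.bidirectional)
        return None


def step(s: int, a: Action, spec: MazeSpec,
         open_overrides: dict[int, bool] | None = None) -> tuple[int, float]:
    """Deterministic grid step under a concrete barrier configuration.

    Bumping the border, a wall, an obstacle, or a closed barrier (from a
    blocking side) leaves the state unchanged with zero reward.  Entering the
    goal yields ``goal_reward`` and applies the episode convention.
    """
    if not (0 <= s < spec.n_states):
        raise ValueError(f"invalid state {s}")
    a = Action(a)
    if spec.reset == "absorb" and s == spec.goal:
        return s, 0.0
    t = spec.neighbor(s, a)
    if t is None or spec.wall_between(s, t) or t in spec.obstacles:
        return s, 0.0
    hit = spec.barrier_on(s, a)
    if hit is not None:
        idx, blocking_side = hit
        is_open = (open_overrides.get(idx, spec.barriers[idx].truly_open)
                   if open_overrides else spec.barriers[idx].truly_open)
        if blocking_side and not is_open:
            return s, 0.0
    if t == spec.goal:
        nxt = spec.start if spec.reset == "start" else spec.goal
        return nxt, spec.goal_reward
    return t, 0.0


def true_transition_model(spec: MazeSpec) -> tuple[np.ndarray, np.ndarray]:
    """One-hot transition tensor P[s, a, s'] and reward matrix R[s, a]."""
    S, A = spec.n_states, len(ACTIONS)
    P = np.zeros((S, A, S))
    R = np.zeros((S, A))
    for s in range(S):
        for a in ACTIONS:
            s2, r = step(s, a, spec)
            P[s, a, s2] = 1.0
            R[s, a] = r
    return P, R


def expected_transition_model(
    spec: MazeSpec, open_probs: dict[int, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Subjective transition model under per-barrier opening probabilities.

    A blocked-side attempt at barrier ``i`` succeeds with probability
    ``open_probs[i]`` (mass splits between the crossed cell and staying put);
    barriers absent from ``open_probs`` use their true openness.
    """
    S, A = spec.n_states, len(ACTIONS)
    P = np.zeros((S, A, S))
    R = np.zeros((S, A))
    for s in range(S):
        for a in ACTIONS:
            hit = spec.barrier_on(s, a)
            if hit is not None and hit[1] and hit[0] in open_probs:
                p_open = float(open_probs[hit[0]])
                s_open, r_open = step(s, a, spec, open_overrides={hit[0]: True})
                s_closed, _ = step(s, a, spec, open_overrides={hit[0]: False})
                P[s, a, s_open] += p_open
                P[s, a, s_closed] += 1.0 - p_open
                R[s, a] = p_open * r_open
            else:
                s2, r = step(s, a, spec)
                P[s, a, s2] = 1.0
                R[s, a] = r
    return P, R


def belief_open_probs(belief: MazeBeliefState) -> dict[int, float]:
    """Per-barrier opening probabilities implied by a belief state's entries."""
    return {i: predictive_probability(e) for i, e in enumerate(belief.barrier_beliefs)}


def value_iteration(P: np.ndarray, R: np.ndarray, gamma: float,
                    tol: float = 1e-5, max_iter: int = 100_000) -> np.ndarray:
    """Synchronous Bellman backups Q <- R + gamma * P V until the max absolute
    Q change falls below ``tol``."""
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    Q = np.zeros_like(R)
    for _ in range(max_iter):
        V = Q.max(axis=1)
        Q_new = R + gamma * P @ V
        if np.max(np.abs(Q_new - Q)) < tol:
            return Q_new
        Q = Q_new
    raise RuntimeError("value iteration did not converge")


def legal_actions(spec: MazeSpec, s: int) -> list[Action]:
    """Actions that do not aim at a wall, obstacle, or the grid border.

    Barrier edges stay legal: attempting one is how it is learnt about.
    """
    out = []
    for a in ACTIONS:
        t = spec.neighbor(s, a)
        if t is None or t in spec.obstacles or spec.wall_between(s, t):
            continue
        out.append(a)
    return out


def greedy_actions(Q: np.ndarray) -> np.ndarray:
    """Greedy action per state; ties break by lowest action index."""
    return Q.argmax(axis=1)


def reachable_states(spec: MazeSpec, belief: MazeBeliefState, horizon: int) -> set[int]:
    """Physical states reachable from ``belief.s`` within ``horizon`` moves.

    Unresolved barriers are treated optimistically (potentially open); resolved
    entries are honoured.  Entering the goal follows the episode convention.
    """
    overrides = {
        i: e.open if isinstance(e, Resolved) else True
        for i, e in enumerate(belief.barrier_beliefs)
    }
    frontier = {belief.s}
    seen = {belief.s}
    for _ in range(horizon):
        nxt = set()
        for s in frontier:
            for a in ACTIONS:
                s2, _ = step(s, a, spec, open_overrides=overrides)
                if s2 not in seen:
                    seen.add(s2)
                    nxt.add(s2)
        frontier = nxt
        if not frontier:
            break
    return seen


# -- built-in layouts ---------------------------------------------------------

TOLMAN_WIDTH, TOLMAN_HEIGHT = 5, 6


def tolman_maze(
    top_open: bool = False,
    left_open: bool = False,
    with_bottom_barrier: bool = False,
    bottom_open: bool = False,
    bidirectional_bottom: bool = True,
    goal_reward: float = 1.0,
    reset: str = "start",
) -> MazeSpec:
    """Three-corridor detour maze (shortest route 6, detours 8 and 10 moves).

    Barrier order: 0 = "top" (exit of the central corridor, one-directional,
    learnable from below), 1 = "left" (exit of the left corridor), and, when
    ``with_bottom_barrier``, 2 = "bottom" (entrance of the central corridor,
    bidirectional by default so the cell above retains a second usable action).
    """
    W, H = TOLMAN_WIDTH, TOLMAN_HEIGHT
    obstacles = frozenset((r * W + c) for r in range(1, 5) for c in (1, 3))
    barriers = [
        Barrier(cell=4 * W + 2, direction=Action.UP, truly_open=top_open),
        Barrier(cell=4 * W + 0, direction=Action.UP, truly_open=left_open),
    ]
    if with_bottom_barrier:
        barriers.append(
            Barrier(cell=0 * W + 2, direction=Action.UP,
                    bidirectional=bidirectional_bottom, truly_open=bottom_open)
        )
    return MazeSpec(
        width=W, height=H,
        start=0 * W + 2, goal=5 * W + 1,
        obstacles=obstacles, barriers=tuple(barriers),
        goal_reward=goal_reward, reset=reset,
    )


def tolman_central_corridor(spec: MazeSpec) -> list[int]:
    """Cells of the central (shortcut) corridor, entrance to exit."""
    return [r * spec.width + 2 for r in range(1, 5)]


def tmaze(cued: bool = False, barrier_open: bool = False) -> MazeSpec:
    """T-maze: 3-cell central stem, see-through barrier at the stem top, two
    side arms on the crossbar.  ``cued`` places the reward at the right arm end."""
    W, H = 5, 4
    obstacles = frozenset((r * W + c) for r in range(0, 3) for c in (0, 1, 3, 4))
    return MazeSpec(
        width=W, height=H,
        start=0 * W + 2, goal=(3 * W + 4) if cued else None,
        obstacles=obstacles,
        barriers=(Barrier(cell=2 * W + 2, direction=Action.UP, truly_open=barrier_open),),
        goal_reward=1.0 if cued else 0.0,
        reset="start",
    )


def tmaze_arms(spec: MazeSpec) -> tuple[list[int], list[int]]:
    """(left arm cells, right arm cells) of the T-maze crossbar."""
    W = spec.width
    return [3 * W + 0, 3 * W + 1], [3 * W + 3, 3 * W + 4]


def spec_to_dict(spec: MazeSpec) -> dict:
    """Plain (JSON/YAML-compatible) representation of a maze layout."""
    return {
        "width": spec.width, "height": spec.height,
        "start": spec.start, "goal": spec.goal,
        "walls": sorted(list(e) for e in spec.walls),
        "obstacles": sorted(spec.obstacles),
        "barriers": [{"cell": b.cell, "direction": Action(b.direction).name,
                      "bidirectional": b.bidirectional,
                      "open": b.truly_open} for b in spec.barriers],
        "goal_reward": spec.goal_reward,
        "reset": spec.reset,
    }


def spec_from_dict(d: dict) -> MazeSpec:
    """Load a maze layout from its plain-text record."""
    return MazeSpec(
        width=int(d["width"]), height=int(d["height"]),
        start=int(d["start"]),
        goal=None if d.get("goal") is None else int(d["goal"]),
        walls=frozenset(tuple(e) for e in d.get("walls", [])),
        obstacles=frozenset(int(c) for c in d.get("obstacles", [])),
        barriers=tuple(Barrier(cell=int(b["cell"]),
                               direction=Action[b["direction"]],
                               bidirectional=bool(b.get("bidirectional", False)),
                               truly_open=bool(b.get("open", False)))
                       for b in d.get("barriers", [])),
        goal_reward=float(d.get("goal_reward", 1.0)),
        reset=d.get("reset", "start"),
    )


def with_barrier_open(spec: MazeSpec, index: int, open: bool = True) -> MazeSpec:
    """Copy of ``spec`` with one barrier's true openness toggled."""
    barriers = list(spec.barriers)
    barriers[index] = replace(barriers[index], truly_open=open)
    return replace(spec, barriers=tuple(barriers))
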