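"""Exploratory replay: EVB-prioritised Bellman backups in belief space.

Two engines share the same Gain x Need prioritisation:

* :class:`BanditBeliefReplay` schedules backups in a finite-horizon bandit
  belief tree, with Need computed exactly (discounted path probability under
  the softmax behavioural policy).
* :class:`MazeBeliefReplay` schedules backups over the finite discretisation
  ``disc_h(B)`` of a barrier maze's belief space, with Need estimated by
  Monte-Carlo rollouts plus a certainty-equivalent tail.

A backup in the maze can *generalise*: the same physical action value is
shared by every discretised belief state with the same physical state and the
same belief about the attempted barrier, so one candidate updates the whole
affected set at once and its EVB sums Need-weighted Gain over that set (the
outer sum over belief space in the prioritisation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .agent import softmax_policy
from .bandit import BeliefTree
from .beliefs import (BetaBelief, MazeBeliefState, _entry_key,
                      barrier_combinations, predictive_probability)
from .maze import (ACTIONS, MazeSpec, belief_open_probs,
                   expected_transition_model, step)


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------


def gain_belief(q_row: np.ndarray, a_k: int, new_value: float, beta: float) -> float:
    """Local policy-improvement term at one belief state.

    sum_a [pi_new(a|b) - pi_old(a|b)] Q_new(b, a), with softmax(beta) policies
    over the belief state's action values before/after writing ``new_value``
    into action ``a_k``.
    """
    q_new = q_row.copy()
    q_new[a_k] = new_value
    pi_old = softmax_policy(q_row, beta)
    pi_new = softmax_policy(q_new, beta)
    return float((pi_new - pi_old) @ q_new)


def children_of(spec: MazeSpec, b: MazeBeliefState, a: int):
    """Children set C(b, a): the belief states one action can lead to.

    Attempting an unresolved barrier from a blocking side forks into
    (crossed, belief resolved open) with the predictive probability and
    (stayed, belief resolved closed) with the complement.  Every other move
    has a single child with unchanged belief.  Returns a list of
    (child_belief, probability, reward) with probabilities summing to 1.
    """
    hit = spec.barrier_on(b.s, a)
    if hit is not None and hit[1]:
        bidx = hit[0]
        entry = b.barrier_beliefs[bidx]
        if isinstance(entry, BetaBelief):
            p_open = predictive_probability(entry)
            s_open, r_open = step(b.s, a, spec, open_overrides={bidx: True})
            child_open = b.with_state(s_open).resolve(bidx, True)
            child_closed = b.resolve(bidx, False)  # physical state unchanged
            return [(child_open, p_open, r_open), (child_closed, 1.0 - p_open, 0.0)]
        s2, r = step(b.s, a, spec, open_overrides={bidx: entry.open})
        return [(b.with_state(s2), 1.0, r)]
    overrides = {i: e.open for i, e in enumerate(b.barrier_beliefs)
                 if not isinstance(e, BetaBelief)}
    s2, r = step(b.s, a, spec, open_overrides=overrides)
    return [(b.with_state(s2), 1.0, r)]


def belief_backup(q_of: Callable, child_set, gamma: float) -> float:
    """One-step Bellman value through a children set (unit learning rate):
    sum_{b'} T(b'|b,a) [R(b') + gamma max_a' Q(b', a')]."""
    return float(sum(p * (r + gamma * float(np.max(q_of(bc))))
                     for bc, p, r in child_set))


@dataclass(frozen=True)
class ExecutedUpdate:
    """One committed replay update (one element of a bout)."""

    step: int
    s_k: int            # physical state (bandit: node index)
    a_k: int
    belief_label: tuple
    gain: float
    need: float
    evb: float
    is_sequence: bool = False
    seq_id: int = -1
    seq_pos: int = 0
    seq_len: int = 1
    direction: str = "single"


# ---------------------------------------------------------------------------
# bandit engine
# ---------------------------------------------------------------------------


class TreeElement(NamedTuple):
    node_index: int
    a: int

    @property
    def physical(self) -> int:
        # bandits have no physical states; node identity prevents loops
        return self.node_index


class BanditBeliefReplay:
    """EVB-prioritised replay over an (unmerged) bandit belief tree.

    Candidates are every (internal node, arm).  Need is exact: the root has
    Need 1 and each node accumulates gamma * pi_old(a|b) * T(b'|b, a) along
    its unique path from the root.  A backup rewrites one action value with
    its one-step Bellman value; Gain compares the softmax policies at that
    node before/after the hypothetical write.
    """

    def __init__(self, tree: BeliefTree, beta: float, xi: float):
        if xi <= 0:
            raise ValueError("xi must be positive")
        self.tree = tree
        self.beta = beta
        self.xi = xi
        self.gamma = tree.gamma
        self._internal = tree.internal_nodes()
        self._parent = {}
        for n in tree.nodes:
            for branch in n.children:
                for child, _, _ in branch:
                    self._parent[child.index] = n

    def _q(self, node, overlay):
        if overlay and node.index in overlay:
            return overlay[node.index]
        return node.q_mb

    def _backup(self, node, a: int, overlay) -> float:
        return float(sum(
            p * (r + self.gamma * self._q(child, overlay).max())
            for child, p, r in node.children[a]
        ))

    def compute_need(self, overlay=None) -> np.ndarray:
        """Exact Need per node: gamma-discounted reach probability under the
        current softmax behavioural policy."""
        need = np.zeros(len(self.tree.nodes))
        need[self.tree.root.index] = 1.0
        for node in self.tree.nodes:  # breadth-first: parents before children
            if node.is_leaf:
                continue
            pi = softmax_policy(self._q(node, overlay), self.beta)
            for a, branch in enumerate(node.children):
                for child, p, _ in branch:
                    need[child.index] = need[node.index] * pi[a] * p * self.gamma
        return need

    # -- sequence-engine protocol -------------------------------------------

    def single_elements(self) -> list[TreeElement]:
        return [TreeElement(n.index, a)
                for n in self._internal for a in range(n.state.n_arms)]

    def element_successors(self, el: TreeElement) -> list[TreeElement]:
        node = self.tree.nodes[el.node_index]
        return [TreeElement(child.index, a)
                for child, _, _ in node.children[el.a]
                if not child.is_leaf
                for a in range(child.state.n_arms)]

    def element_predecessors(self, el: TreeElement) -> list[TreeElement]:
        parent = self._parent.get(el.node_index)
        if parent is None:
            return []
        return [TreeElement(parent.index, a)
                for a, branch in enumerate(parent.children)
                if any(c.index == el.node_index for c, _, _ in branch)]

    def evaluate_elements(self, elements, need, overlay: dict | None = None):
        """Apply elements in order on a scratch copy; per-element EVB is
        Need x Gain at the element's node given the intermediate values."""
        overlay = dict(overlay or {})
        per_elem = []
        for el in elements:
            node = self.tree.nodes[el.node_index]
            row = self._q(node, overlay).copy()
            v = self._backup(node, el.a, overlay)
            g = gain_belief(row, el.a, v, self.beta)
            per_elem.append((float(need[node.index]) * g, g, v))
            row[el.a] = v
            overlay[node.index] = row
        total = float(sum(e for e, _, _ in per_elem))
        return total, per_elem, overlay

    def apply_elements(self, elements) -> None:
        for el in elements:
            node = self.tree.nodes[el.node_index]
            node.q_mb[el.a] = self._backup(node, el.a, None)

    def element_label(self, el: TreeElement) -> tuple:
        return ("depth", self.tree.nodes[el.node_index].depth)

    def element_need(self, el: TreeElement, need) -> float:
        return float(need[el.node_index])

    def sequence_filters(self, direction: str):
        return None, None  # tree replay competes freely, no anchoring

    def run(self, sequences: bool = False, max_length: int | None = None,
            max_updates: int = 100_000,
            beam_width: int | None = None) -> list[ExecutedUpdate]:
        L = max_length or self.tree.horizon
        return _run_loop(self, self.compute_need, sequences, L,
                         max_updates, beam_width, anchored=False)

    def root_greedy_value(self) -> float:
        return float(self.tree.root.q_mb.max())

    def evaluated_policy_value(self) -> float:
        from .bandit import evaluate_greedy_policy
        return evaluate_greedy_policy(self.tree)


# ---------------------------------------------------------------------------
# shared replay loop (singles + optional sequences)
# ---------------------------------------------------------------------------


def _run_loop(engine, need_fn, sequences: bool, L: int, max_updates: int,
              beam_width: int | None,
              anchored: bool = False) -> list[ExecutedUpdate]:
    """Greedy max-EVB execution until the best candidate falls below xi.

    On (near-)ties, the event encountered first in a deterministic order wins
    and sequence candidates are visited after singles, so a single action
    beats an equal-EVB sequence (fewer updates for equal benefit).

    With ``anchored`` sequence events (maze scenarios), a replay event is a
    coherent trajectory whose far end sits at a critical decision point; an
    anchored sequence clearing xi is executed in preference to lone
    single-action updates, which serve as the fallback when no trajectory
    event clears the threshold.
    """
    from .sequences import generate_sequences

    executed: list[ExecutedUpdate] = []
    seq_counter = 0
    while len(executed) < max_updates:
        need = need_fn()
        best_elems, best_meta, best_evb, best_dir = None, None, -np.inf, "single"
        seq_elems, seq_meta, seq_evb, seq_dir = None, None, -np.inf, "single"
        if sequences:
            for direction in ("reverse", "forward"):
                seed_f, emit_f = engine.sequence_filters(direction)
                for seq in generate_sequences(engine, need, L, direction,
                                              engine.xi, beam_width=beam_width,
                                              seed_filter=seed_f,
                                              emit_filter=emit_f):
                    better = seq.evb > seq_evb + 1e-15
                    if anchored and not better:
                        # equal-benefit anchored events: the longer chain wins
                        # (it links further between critical decision points)
                        better = (seq.evb > seq_evb - 1e-12
                                  and seq_elems is not None
                                  and len(seq.elements) > len(seq_elems))
                    if better:
                        seq_elems = list(seq.elements)
                        seq_meta = seq.per_element
                        seq_evb, seq_dir = seq.evb, direction
        if anchored and seq_elems is not None and seq_evb >= engine.xi:
            best_elems, best_meta, best_evb, best_dir = (
                seq_elems, seq_meta, seq_evb, seq_dir)
        else:
            for el in engine.single_elements():
                evb, per, _ = engine.evaluate_elements([el], need)
                if evb > best_evb + 1e-15:
                    best_elems, best_meta, best_evb, best_dir = [el], per, evb, "single"
            if not anchored and seq_evb > best_evb + 1e-15:
                best_elems, best_meta, best_evb, best_dir = (
                    seq_elems, seq_meta, seq_evb, seq_dir)
        if best_elems is None or best_evb < engine.xi:
            break
        engine.apply_elements(best_elems)
        is_seq = len(best_elems) > 1
        if is_seq:
            seq_counter += 1
        for pos, (el, (evb_e, g, _)) in enumerate(zip(best_elems, best_meta)):
            executed.append(ExecutedUpdate(
                step=len(executed), s_k=el.physical, a_k=el.a,
                belief_label=engine.element_label(el), gain=g,
                need=engine.element_need(el, need), evb=evb_e,
                is_sequence=is_seq, seq_id=seq_counter if is_seq else -1,
                seq_pos=pos, seq_len=len(best_elems),
                direction=best_dir if is_seq else "single"))
    return executed


# ---------------------------------------------------------------------------
# Monte-Carlo Need (maze)
# ---------------------------------------------------------------------------


class MazeElement(NamedTuple):
    s: int
    ci: int  # index into the engine's belief-combination list
    a: int

    @property
    def physical(self) -> int:
        return self.s


@dataclass
class NeedMap:
    """Need over ``disc_h(B)`` plus rollout bookkeeping."""

    need: dict[tuple[int, int], float]                # (s, ci) -> Need
    first_hit_discount: dict[tuple[int, int], float]  # mean gamma^{K_i}, 0 if unhit
    first_hit_discount_sq: dict[tuple[int, int], float]  # mean gamma^{2 K_i}
    hit_fraction: dict[tuple[int, int], float]
    n_rollouts: int

    def __getitem__(self, key: tuple[int, int]) -> float:
        return self.need.get(key, 0.0)


def mc_need(
    spec: MazeSpec,
    root: MazeBeliefState,
    configs: list[tuple],
    q_by_config: np.ndarray,
    beta: float,
    gamma: float,
    n_rollouts: int,
    rng: np.random.Generator,
    eps: float = 1e-5,
    tail: str = "renewal",
) -> NeedMap:
    """Monte-Carlo estimator of exploratory Need over the discretised beliefs.

    ``n_rollouts`` trajectories start at the root belief state; decisions
    follow the softmax(beta) policy over ``q_by_config`` and transitions
    follow the expected model, with sampled barrier attempts resolving the
    belief hard (open or closed, no residual uncertainty).  Each trajectory
    runs while gamma^d > eps and records the first-hit step K_i(b) of every
    discretised belief state it meets; unhit trajectories contribute zero.

    The within-horizon term gamma^{K_i(b)} is combined with a
    certainty-equivalent tail that assumes stationary dynamics beyond the
    first hit.  ``tail='renewal'`` multiplies by the diagonal resolvent entry
    [(I - gamma T_c)^-1]_(s, s) -- exactly unbiased for the discounted
    successor representation once no uncertainty remains (strong Markov
    property).  ``tail='series'`` adds the series
    [sum_{j > K_i} (gamma T_c)^j]_(s_rho, s) instead.
    """
    if n_rollouts < 1:
        raise ValueError("n_rollouts must be >= 1")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if tail not in ("renewal", "series"):
        raise ValueError("tail must be 'renewal' or 'series'")
    S, A = spec.n_states, len(ACTIONS)
    n_c = len(configs)
    ci_of = {c: i for i, c in enumerate(configs)}
    root_ci = ci_of[root.barrier_beliefs]
    max_steps = int(np.floor(np.log(eps) / np.log(gamma)))

    pis = softmax_policy(q_by_config, beta)  # (n_c, S, A)

    # sampled-outcome tables: outcome 0 with prob out_p, else outcome 1
    out_s = np.zeros((n_c, S, A, 2), dtype=np.int32)
    out_c = np.zeros((n_c, S, A, 2), dtype=np.int32)
    out_p = np.ones((n_c, S, A))
    for ci, combo in enumerate(configs):
        for s in range(S):
            b = MazeBeliefState(s, combo)
            for a in ACTIONS:
                kids = children_of(spec, b, a)
                out_s[ci, s, a, 0] = kids[0][0].s
                out_c[ci, s, a, 0] = ci_of[kids[0][0].barrier_beliefs]
                out_p[ci, s, a] = kids[0][1]
                last = kids[-1][0]
                out_s[ci, s, a, 1] = last.s
                out_c[ci, s, a, 1] = ci_of[last.barrier_beliefs]

    # policy-weighted expected state-to-state operator per belief combination
    T_c = np.zeros((n_c, S, S))
    for ci, combo in enumerate(configs):
        P, _ = expected_transition_model(
            spec, belief_open_probs(MazeBeliefState(0, combo)))
        T_c[ci] = np.einsum("sa,sax->sx", pis[ci], P)
    if not np.allclose(T_c.sum(axis=2), 1.0, atol=1e-8):
        raise ValueError("invalid policy-transition operator: rows must sum to 1")
    M_c = np.stack([np.linalg.solve(np.eye(S) - gamma * T_c[ci], np.eye(S))
                    for ci in range(n_c)])

    # vectorised rollouts
    N = n_rollouts
    first_hit = np.full((N, n_c * S), -1, dtype=np.int32)
    cur_s = np.full(N, root.s, dtype=np.int32)
    cur_c = np.full(N, root_ci, dtype=np.int32)
    rows = np.arange(N)
    for d in range(max_steps + 1):
        flat = cur_c * S + cur_s
        unseen = first_hit[rows, flat] < 0
        first_hit[rows[unseen], flat[unseen]] = d
        if d == max_steps:
            break
        p_rows = pis[cur_c, cur_s]
        acts = (rng.random(N)[:, None] > np.cumsum(p_rows, axis=1)).sum(axis=1)
        acts = np.minimum(acts, A - 1)
        branch = np.where(rng.random(N) < out_p[cur_c, cur_s, acts], 0, 1)
        nxt_s = out_s[cur_c, cur_s, acts, branch]
        nxt_c = out_c[cur_c, cur_s, acts, branch]
        cur_s, cur_c = nxt_s, nxt_c

    hit = first_hit >= 0
    disc_g = np.where(hit, np.power(gamma, np.maximum(first_hit, 0)), 0.0)
    mean_g = disc_g.mean(axis=0)
    mean_g2 = (disc_g ** 2).mean(axis=0)
    hit_frac = hit.mean(axis=0)

    tails = None
    if tail == "series":
        # row s_rho of (gamma T_c)^{K+1} (I - gamma T_c)^{-1}, K = 0..max_steps
        tails = np.zeros((n_c, max_steps + 1, S))
        for ci in range(n_c):
            v = np.zeros(S)
            v[root.s] = 1.0
            for k in range(max_steps + 1):
                v = gamma * (v @ T_c[ci])
                tails[ci, k] = v @ M_c[ci]

    need: dict[tuple[int, int], float] = {}
    fh: dict[tuple[int, int], float] = {}
    fh2: dict[tuple[int, int], float] = {}
    hf: dict[tuple[int, int], float] = {}
    for ci in range(n_c):
        for s in range(S):
            col = ci * S + s
            fh2[(s, ci)] = float(mean_g2[col])
            if hit_frac[col] == 0.0:
                need[(s, ci)] = 0.0
                fh[(s, ci)] = 0.0
                hf[(s, ci)] = 0.0
                continue
            if tail == "renewal":
                val = mean_g[col] * M_c[ci, s, s]
            else:
                ks = first_hit[hit[:, col], col]
                val = float(np.mean(
                    np.power(gamma, ks) + tails[ci, ks, s])) * hit_frac[col]
                # mean over *all* N trajectories (unhit contribute zero)
            need[(s, ci)] = float(val)
            fh[(s, ci)] = float(mean_g[col])
            hf[(s, ci)] = float(hit_frac[col])
    return NeedMap(need, fh, fh2, hf, N)


# ---------------------------------------------------------------------------
# maze engine
# ---------------------------------------------------------------------------


class MazeCandidate(NamedTuple):
    """A generalising update: physical (s, a) plus the attempted-barrier entry
    (None when the action does not probe an unresolved barrier)."""

    s: int
    a: int
    rel: tuple | None  # (barrier index, entry key)


class MazeBeliefReplay:
    """EVB-prioritised exploratory replay over a maze's discretised beliefs.

    Action values Q_MB(b, a) are stored per (physical state, belief
    combination) and initialised lazily from the agent's model-free table.
    Candidates generalise across belief combinations that agree on the
    attempted barrier's entry; Need comes from :func:`mc_need` and is
    refreshed after every executed update by default.
    """

    def __init__(self, spec: MazeSpec, root: MazeBeliefState, q_mf: np.ndarray,
                 gamma: float, beta: float, xi: float, horizon: int,
                 n_rollouts: int = 1000, need_eps: float = 1e-5,
                 seed: int | np.random.SeedSequence = 0,
                 need_refresh: str = "every", need_tail: str = "renewal",
                 beam_width: int | None = 64, anchored: bool = True):
        if xi <= 0:
            raise ValueError("xi must be positive")
        if need_refresh not in ("every", "bout"):
            raise ValueError("need_refresh must be 'every' or 'bout'")
        self.spec = spec
        self.root = root
        self.q_mf = np.asarray(q_mf, dtype=float)
        self.gamma, self.beta, self.xi = gamma, beta, xi
        self.horizon = horizon
        self.n_rollouts = n_rollouts
        self.need_eps = need_eps
        self.need_refresh = need_refresh
        self.need_tail = need_tail
        self.beam_width = beam_width
        self.anchored = anchored
        self._ss = (seed if isinstance(seed, np.random.SeedSequence)
                    else np.random.SeedSequence(seed))

        self.configs = barrier_combinations(root.barrier_beliefs)
        self.ci_of = {c: i for i, c in enumerate(self.configs)}
        self.root_ci = self.ci_of[root.barrier_beliefs]
        from .beliefs import discretize_reachable
        disc_beliefs = discretize_reachable(root, horizon, spec, joint=True)
        self.disc = {(b.s, self.ci_of[b.barrier_beliefs]) for b in disc_beliefs}
        self.disc_states = sorted({s for s, _ in self.disc})
        self._table: dict[tuple[int, int], np.ndarray] = {}
        self._kids: dict[tuple[int, int, int], list] = {}
        self._root_writes: set[tuple[int, int]] = set()
        self._need_cache: NeedMap | None = None
        self._pred: dict[tuple[int, int], list[MazeElement]] | None = None

    # -- values --------------------------------------------------------------

    def q_row(self, s: int, ci: int, overlay: dict | None = None) -> np.ndarray:
        key = (s, ci)
        if overlay and key in overlay:
            return overlay[key]
        if key not in self._table:
            self._table[key] = self.q_mf[s].copy()
        return self._table[key]

    def children(self, s: int, ci: int, a: int) -> list[tuple[int, int, float, float]]:
        """Cached children as (s', ci', probability, reward) tuples."""
        key = (s, ci, a)
        if key not in self._kids:
            b = MazeBeliefState(s, self.configs[ci])
            self._kids[key] = [
                (bc.s, self.ci_of[bc.barrier_beliefs], p, r)
                for bc, p, r in children_of(self.spec, b, a)
            ]
        return self._kids[key]

    def backup(self, s: int, ci: int, a: int, overlay: dict | None = None) -> float:
        return float(sum(
            p * (r + self.gamma * self.q_row(s2, c2, overlay).max())
            for s2, c2, p, r in self.children(s, ci, a)
        ))

    # -- candidates ----------------------------------------------------------

    def candidates(self) -> list[MazeCandidate]:
        seen = set()
        out = []
        for s, ci in sorted(self.disc):
            for a in ACTIONS:
                cand = self.candidate_of(MazeElement(s, ci, int(a)))
                if cand not in seen:
                    seen.add(cand)
                    out.append(cand)
        return out

    def affected_configs(self, cand: MazeCandidate) -> list[int]:
        """Belief combinations the candidate's write generalises to: those in
        the discretisation that agree on the attempted barrier's entry."""
        if cand.rel is None:
            cis = range(len(self.configs))
        else:
            bidx, ek = cand.rel
            cis = (ci for ci, c in enumerate(self.configs)
                   if _entry_key(c[bidx]) == ek)
        return [ci for ci in cis if (cand.s, ci) in self.disc]

    def eval_candidate(self, cand: MazeCandidate, need: NeedMap,
                       overlay: dict | None = None):
        """Generalised EVB: sum over affected belief states of Need x Gain,
        each with its own one-step backup value."""
        evb = 0.0
        details = []
        for ci in self.affected_configs(cand):
            row = self.q_row(cand.s, ci, overlay)
            v = self.backup(cand.s, ci, cand.a, overlay)
            g = gain_belief(row, cand.a, v, self.beta)
            evb += need[(cand.s, ci)] * g
            details.append((ci, g, v))
        return evb, details

    def apply_candidate(self, cand: MazeCandidate, details) -> None:
        for ci, _, v in details:
            self.q_row(cand.s, ci)[cand.a] = v
            if ci == self.root_ci:
                self._root_writes.add((cand.s, cand.a))

    def candidate_of(self, el: MazeElement) -> MazeCandidate:
        hit = self.spec.barrier_on(el.s, el.a)
        if hit is not None and hit[1]:
            return MazeCandidate(el.s, el.a,
                                 (hit[0], _entry_key(self.configs[el.ci][hit[0]])))
        return MazeCandidate(el.s, el.a, None)

    # -- sequence-engine protocol ---------------------------------------------

    def single_elements(self) -> list[MazeElement]:
        # one representative element per generalising candidate
        seen = set()
        els = []
        for s, ci in sorted(self.disc):
            for a in ACTIONS:
                el = MazeElement(s, ci, int(a))
                cand = self.candidate_of(el)
                if cand not in seen:
                    seen.add(cand)
                    els.append(el)
        return els

    def element_successors(self, el: MazeElement) -> list[MazeElement]:
        out = []
        for s2, c2, _, _ in self.children(el.s, el.ci, el.a):
            if (s2, c2) in self.disc:
                out.extend(MazeElement(s2, c2, int(a)) for a in ACTIONS)
        return out

    def element_predecessors(self, el: MazeElement) -> list[MazeElement]:
        if self._pred is None:
            pred: dict[tuple[int, int], list[MazeElement]] = {}
            for s, ci in self.disc:
                for a in ACTIONS:
                    for s2, c2, p, _ in self.children(s, ci, a):
                        if p > 0 and (s2, c2) in self.disc and (s2, c2) != (s, ci):
                            pred.setdefault((s2, c2), []).append(
                                MazeElement(s, ci, int(a)))
            self._pred = pred
        return self._pred.get((el.s, el.ci), [])

    def evaluate_elements(self, elements, need: NeedMap,
                          overlay: dict | None = None):
        """Apply elements (with generalisation) in order on a scratch copy."""
        overlay = {k: v.copy() for k, v in (overlay or {}).items()}
        per_elem = []
        for el in elements:
            cand = self.candidate_of(el)
            evb_el = 0.0
            own_gain = 0.0
            own_v = np.nan
            writes = []
            for ci in self.affected_configs(cand):
                row = self.q_row(el.s, ci, overlay)
                v = self.backup(el.s, ci, el.a, overlay)
                g = gain_belief(row, el.a, v, self.beta)
                evb_el += need[(el.s, ci)] * g
                writes.append((ci, v))
                if ci == el.ci:
                    own_gain, own_v = g, v
            for ci, v in writes:
                row = self.q_row(el.s, ci, overlay).copy()
                row[el.a] = v
                overlay[(el.s, ci)] = row
            per_elem.append((evb_el, own_gain, own_v))
        total = float(sum(e for e, _, _ in per_elem))
        return total, per_elem, overlay

    def apply_elements(self, elements) -> None:
        for el in elements:
            cand = self.candidate_of(el)
            _, details = self.eval_candidate(cand, _ZERO_NEED)
            self.apply_candidate(cand, details)

    def element_label(self, el: MazeElement) -> tuple:
        return tuple(_entry_key(e) for e in self.configs[el.ci])

    def element_need(self, el: MazeElement, need: NeedMap) -> float:
        return need[(el.s, el.ci)]

    def is_source_element(self, el: MazeElement) -> bool:
        """An element anchoring a trajectory event at a critical decision
        point: its action attempts a barrier (from a teaching side) or can
        enter the goal."""
        hit = self.spec.barrier_on(el.s, el.a)
        if hit is not None and hit[1]:
            return True
        return any(r > 0 for _, _, _, r in self.children(el.s, el.ci, el.a))

    def sequence_filters(self, direction: str):
        """Anchoring: a replayed trajectory's far end (the first executed
        element of a reverse event, the final element of a forward event)
        must be a source element."""
        if not self.anchored:
            return None, None
        if direction == "reverse":
            return self.is_source_element, None
        return None, lambda elements: self.is_source_element(elements[-1])

    # -- Need ----------------------------------------------------------------

    def q_by_config(self) -> np.ndarray:
        q = np.repeat(self.q_mf[None, :, :], len(self.configs), axis=0)
        for (s, ci), row in self._table.items():
            q[ci, s] = row
        return q

    def compute_need(self) -> NeedMap:
        rng = np.random.default_rng(self._ss.spawn(1)[0])
        return mc_need(self.spec, self.root, self.configs, self.q_by_config(),
                       self.beta, self.gamma, self.n_rollouts, rng,
                       eps=self.need_eps, tail=self.need_tail)

    def _need_fn(self) -> NeedMap:
        if self._need_cache is None or self.need_refresh == "every":
            self._need_cache = self.compute_need()
        return self._need_cache

    # -- replay loop -----------------------------------------------------------

    def run(self, sequences: bool = False, max_length: int | None = None,
            max_updates: int = 500) -> list[ExecutedUpdate]:
        L = max_length or self.horizon
        return _run_loop(self, self._need_fn, sequences, L, max_updates,
                         self.beam_width, anchored=self.anchored)

    def write_back(self) -> np.ndarray:
        """New model-free policy: root-belief Q_MB updates written through to
        the model-free table at their physical states."""
        q_new = self.q_mf.copy()
        for s, a in self._root_writes:
            q_new[s, a] = self._table[(s, self.root_ci)][a]
        return q_new


class _ZeroNeed:
    def __getitem__(self, key):
        return 0.0


_ZERO_NEED = _ZeroNeed()


def evb_belief(engine: MazeBeliefReplay, cand: MazeCandidate,
               need: NeedMap) -> float:
    """EVB of one generalising candidate under a given Need map."""
    evb, _ = engine.eval_candidate(cand, need)
    return evb


def exploratory_replay_loop(engine, sequences: bool = False,
                            max_length: int | None = None,
                            max_updates: int | None = None):
    """Run a replay bout on either engine.

    Returns ``(executed updates, new model-free Q)`` for the maze engine and
    ``(executed updates, None)`` for the bandit engine (bandit replay acts on
    the tree's values directly).
    """
    kwargs = {} if max_updates is None else {"max_updates": max_updates}
    executed = engine.run(sequences=sequences, max_length=max_length, **kwargs)
    q_new = engine.write_back() if isinstance(engine, MazeBeliefReplay) else None
    return executed, q_new
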