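"""Fully-observed (known-environment) prioritised replay: Gain x Need over the
agent's memory buffer, plus the count-based exploration-bonus update.

This is the baseline scheme that the belief-space machinery generalises; it
reproduces the exploitative replay of an agent that assumes its learned model
is the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import AgentState, softmax_policy


@dataclass(frozen=True)
class ReplayCandidate:
    s_k: int
    a_k: int
    gain: float
    need: float

    @property
    def evb(self) -> float:
        return self.gain * self.need


def policy_transition_operator(P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """State-to-state operator T^pi[s, s'] = sum_a pi(a|s) P(s'|s, a)."""
    return np.einsum("sa,sax->sx", pi, P)


def need_md(T_pi: np.ndarray, s: int, gamma: float) -> np.ndarray:
    """Discounted expected future occupancy from ``s``: the (s, .) row of the
    resolvent (I - gamma T^pi)^-1."""
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    n = T_pi.shape[0]
    try:
        M = np.linalg.solve(np.eye(n) - gamma * T_pi, np.eye(n))
    except np.linalg.LinAlgError as err:
        raise ValueError("invalid policy-transition operator") from err
    return M[s]


def gain_md(q_row: np.ndarray, a_k: int, backup_value: float, beta: float) -> float:
    """Local policy-improvement term of one hypothetical backup.

    ``q_row`` holds the pre-update Q(s_k, .); the update writes
    ``backup_value`` into action ``a_k``.  Gain = sum_a [pi_new - pi_old] Q_new
    with softmax(beta) policies.
    """
    q_new = q_row.copy()
    q_new[a_k] = backup_value
    pi_old = softmax_policy(q_row, beta)
    pi_new = softmax_policy(q_new, beta)
    return float((pi_new - pi_old) @ q_new)


def replay_loop(agent: AgentState, s_now: int, xi: float,
                max_updates: int = 200) -> list[ReplayCandidate]:
    """Execute memory-buffer backups in max-EVB order until max EVB < xi.

    Each iteration scores every stored experience (s, a, r, s') by
    Gain x Need, executes the best backup (one-step Bellman value through the
    stored experience), then refreshes the behavioural policy and Need.  Need
    is computed from the *learned* transition model under the softmax policy,
    matching the agent's subjective planning.  Ties break by earliest
    memory-buffer insertion.
    """
    if xi <= 0:
        raise ValueError("xi must be positive")
    executed: list[ReplayCandidate] = []
    for _ in range(max_updates):
        if not agent.memory:
            break
        pi = agent.policy()
        T_pi = policy_transition_operator(agent.t_hat, pi)
        need = need_md(T_pi, s_now, agent.gamma)
        best: ReplayCandidate | None = None
        for (s, a, r, s2) in agent.memory.values():
            new_q = r + agent.gamma * agent.q_mf[s2].max()
            g = gain_md(agent.q_mf[s], a, new_q, agent.beta)
            cand = ReplayCandidate(s, a, g, float(need[s]))
            if best is None or cand.evb > best.evb:
                best = cand
        if best is None or best.evb < xi:
            break
        s, a, r, s2 = agent.memory[(best.s_k, best.a_k)]
        agent.q_mf[s, a] = r + agent.gamma * agent.q_mf[s2].max()
        executed.append(best)
    return executed


def dyna_q_plus_update(agent: AgentState, s: int, a: int, r: float, s2: int,
                       epsilon: float, staleness_count: float) -> float:
    """Q-learning update with the recency bonus epsilon * sqrt(#(s,a)) added to
    the reward inside the TD target."""
    if staleness_count < 0:
        raise ValueError("staleness_count must be >= 0")
    bonus = epsilon * np.sqrt(staleness_count)
    td = (r + bonus) + agent.gamma * agent.q_mf[s2].max() - agent.q_mf[s, a]
    agent.q_mf[s, a] += agent.alpha * td
    return float(agent.q_mf[s, a])
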