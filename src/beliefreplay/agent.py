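"""Online model-free learner: Q-learning, softmax control, forgetting, and a
one-slot-per-(s,a) experience memory with transition-model learning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maze import ACTIONS, MazeSpec, true_transition_model


def softmax_policy(q_values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax action probabilities p(a) ~ exp(beta * Q(s, a)).

    Works on a single state's Q row or a full (S, A) table (row-wise).
    Numerically stabilised by max-subtraction; beta = 0 gives uniform.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    q = np.asarray(q_values, dtype=float)
    z = beta * q
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AgentState:
    """Tabular model-free agent with forgetting and a learned transition model."""

    q_mf: np.ndarray          # (S, A)
    q_init: np.ndarray        # forgetting attractor
    alpha: float              # learning rate
    beta: float               # softmax inverse temperature
    gamma: float              # discount
    phi_mf: float = 0.0       # forgetting rate
    t_hat: np.ndarray = None  # (S, A, S) learned transition model  # type: ignore
    r_hat: np.ndarray = None  # (S, A) learned one-step rewards     # type: ignore
    # most-recent experience per (s, a), in insertion order
    memory: dict[tuple[int, int], tuple[int, int, float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 <= self.phi_mf <= 1.0):
            raise ValueError("phi_mf must lie in [0, 1]")

    @classmethod
    def for_maze(cls, spec: MazeSpec, alpha: float, beta: float, gamma: float,
                 phi_mf: float = 0.0, q_init: np.ndarray | None = None,
                 known_model: bool = True) -> "AgentState":
        """Fresh agent; the transition model starts at the barrier-free truth
        (the agent initially presumes no barriers are present)."""
        S, A = spec.n_states, len(ACTIONS)
        if q_init is None:
            q_init = np.zeros((S, A))
        open_spec = spec
        if known_model:
            from .maze import with_barrier_open
            for i in range(len(spec.barriers)):
                open_spec = with_barrier_open(open_spec, i, True)
        t_hat, r_hat = true_transition_model(open_spec)
        return cls(q_mf=q_init.copy(), q_init=q_init.copy(), alpha=alpha, beta=beta,
                   gamma=gamma, phi_mf=phi_mf, t_hat=t_hat, r_hat=r_hat)

    def policy(self) -> np.ndarray:
        return softmax_policy(self.q_mf, self.beta)


def q_learning_update(agent: AgentState, s: int, a: int, r: float, s2: int) -> float:
    """Q(s,a) += alpha [r + gamma max_a' Q(s',a') - Q(s,a)]; returns the new value."""
    td = r + agent.gamma * agent.q_mf[s2].max() - agent.q_mf[s, a]
    agent.q_mf[s, a] += agent.alpha * td
    return float(agent.q_mf[s, a])


def forget(agent: AgentState) -> None:
    """Exponential decay of the model-free values toward their initialisation."""
    agent.q_mf *= 1.0 - agent.phi_mf
    agent.q_mf += agent.phi_mf * agent.q_init


def update_transition_model(agent: AgentState, s: int, a: int, s2: int) -> None:
    """Delta-rule row replacement toward one-hot(s'), then renormalisation.

    The unit-step delta rule makes the row one-hot; the normalisation is kept
    as a distinct step even though it is then a no-op.
    """
    row = agent.t_hat[s, a]
    onehot = np.zeros_like(row)
    onehot[s2] = 1.0
    row += onehot - row
    row /= row.sum()


def remember(agent: AgentState, s: int, a: int, r: float, s2: int) -> None:
    """Overwrite the memory slot for (s, a) with the latest experience.

    First-insertion order is preserved (it is the replay tie-break).
    """
    agent.memory[(s, a)] = (s, a, r, s2)
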