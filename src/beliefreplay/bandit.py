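"""Finite-horizon belief trees for Bernoulli bandits and their exact values.

Pulling an unresolved (Beta) arm forks the tree into a success child (with the
arm's predictive probability, immediate reward 1) and a failure child; pulling a
known arm yields a single child carrying its expected reward.  Leaves at the
horizon are initialised to their certainty-equivalent long-run values
``max_k E[mu_k] / (1 - gamma)``.  Internal action values start at 0: values of
yet-to-be-encountered belief states are unknown to the agent.

Nodes with identical beliefs at the same depth are deliberately *not* merged;
the unmerged tree is the object over which replay is prioritised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beliefs import (BanditBeliefState, BetaBelief, KnownPayoff, belief_key,
                      predictive_probability)


@dataclass
class BeliefTreeNode:
    state: BanditBeliefState
    depth: int
    # per action: list of (child, transition probability, immediate reward)
    children: list[list[tuple["BeliefTreeNode", float, float]]] = field(default_factory=list)
    q_mb: np.ndarray = field(default=None)  # type: ignore[assignment]
    index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def value(self) -> float:
        return float(self.q_mb.max())


@dataclass
class BeliefTree:
    root: BeliefTreeNode
    horizon: int
    gamma: float
    nodes: list[BeliefTreeNode] = field(default_factory=list)  # breadth-first

    def internal_nodes(self) -> list[BeliefTreeNode]:
        return [n for n in self.nodes if not n.is_leaf]

    def reset_values(self) -> None:
        """Re-initialise all action values (leaves to CE, internal to 0)."""
        for n in self.nodes:
            n.q_mb = _initial_q(n.state, n.is_leaf, self.gamma)

    def export_edges(self):
        """Edge-list records (parent_key, action, child_key, prob, reward, depth)."""
        rows = []
        for n in self.nodes:
            for a, branch in enumerate(n.children):
                for child, p, r in branch:
                    rows.append((belief_key(n.state), a, belief_key(child.state),
                                 p, r, n.depth))
        return rows


def ce_leaf_value(state: BanditBeliefState, gamma: float) -> float:
    """Certainty-equivalent long-run value: max_k E[mu_k | state] / (1 - gamma)."""
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    return max(state.expected_payoffs()) / (1.0 - gamma)


def _initial_q(state: BanditBeliefState, leaf: bool, gamma: float) -> np.ndarray:
    if leaf:
        # per-arm CE long-run payoffs; the node value (max) is the CE leaf value
        return np.array(state.expected_payoffs()) / (1.0 - gamma)
    return np.zeros(state.n_arms)


def build_tree(prior: BanditBeliefState, horizon: int, gamma: float) -> BeliefTree:
    """Expand the full belief tree to ``horizon`` pulls.

    Sibling order is success child first, then failure, for reproducible replay
    orderings.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    root = BeliefTreeNode(prior, 0)
    nodes = [root]
    frontier = [root]
    for depth in range(horizon):
        nxt = []
        for node in frontier:
            node.children = []
            for k, arm in enumerate(node.state.arms):
                p = predictive_probability(arm)
                branch: list[tuple[BeliefTreeNode, float, float]] = []
                if isinstance(arm, BetaBelief):
                    succ = BeliefTreeNode(node.state.pull(k, True), depth + 1)
                    fail = BeliefTreeNode(node.state.pull(k, False), depth + 1)
                    branch.append((succ, p, 1.0))
                    branch.append((fail, 1.0 - p, 0.0))
                else:
                    same = BeliefTreeNode(node.state, depth + 1)
                    branch.append((same, 1.0, p))
                node.children.append(branch)
                for child, _, _ in branch:
                    nodes.append(child)
                    nxt.append(child)
        frontier = nxt
    tree = BeliefTree(root, horizon, gamma, nodes)
    for i, n in enumerate(tree.nodes):
        n.index = i
    tree.reset_values()
    return tree


def backup(node: BeliefTreeNode, action: int, gamma: float) -> float:
    """One-step Bellman value of ``action`` at ``node`` given current children."""
    return float(sum(p * (r + gamma * child.value())
                     for child, p, r in node.children[action]))


def bayes_optimal_values(tree: BeliefTree) -> dict[str, float]:
    """Exact backward induction from the leaves; fills ``q_mb`` in place.

    Returns the root's optimal value (the Bayes-optimal value for this horizon)
    along with per-action root values.
    """
    for node in reversed(tree.nodes):  # children precede parents in reverse BF order
        if node.is_leaf:
            continue
        for a in range(node.state.n_arms):
            node.q_mb[a] = backup(node, a, tree.gamma)
    return {"root_value": tree.root.value(),
            "root_q": tree.root.q_mb.copy()}


def certainty_equivalent_values(prior: BanditBeliefState, horizon: int,
                                gamma: float) -> dict[str, float]:
    """Backward induction in the fork-free tree with each unresolved arm
    collapsed to its mean (the known-environment planner's value)."""
    collapsed = BanditBeliefState(
        tuple(KnownPayoff(predictive_probability(a)) for a in prior.arms)
    )
    tree = build_tree(collapsed, horizon, gamma)
    out = bayes_optimal_values(tree)
    return {"root_value": out["root_value"], "root_q": out["root_q"], "tree": tree}


def evaluate_greedy_policy(tree: BeliefTree) -> float:
    """Value of the greedy (arg-max of current q_mb) policy at the root,
    propagated exactly through the whole tree with CE leaf values."""

    memo: dict[int, float] = {}

    def v(node: BeliefTreeNode) -> float:
        if node.is_leaf:
            return node.value()
        if node.index in memo:
            return memo[node.index]
        a = int(node.q_mb.argmax())
        val = sum(p * (r + tree.gamma * v(child)) for child, p, r in node.children[a])
        memo[node.index] = val
        return val

    return float(v(tree.root))
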