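"""Built-in study scenarios, run at desk scale.

Every scenario is fully determined by (config, seed).  Parameter defaults
are the package's canonical study conditions (see docs/methods.md): the
bandit example uses softmax beta = 1 with gamma and threshold xi chosen so
the canonical horizon-3 bout terminates after its characteristic five
updates; maze scenarios use a softmax-5 planning policy, replay threshold
0.02, planning horizon 8 and 1000 Need rollouts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agent as agent_mod
from . import bandit as bandit_mod
from . import maze as maze_mod
from . import replay_belief as rb
from . import replay_md
from .agent import AgentState, softmax_policy
from .beliefs import (RESOLVED_CLOSED, BanditBeliefState, BetaBelief,
                      KnownPayoff, MazeBeliefState)
from .maze import Action, tolman_maze, tmaze, value_iteration

# Canonical study conditions (rationale for each default: docs/methods.md).
BANDIT_DEFAULTS = {
    "gamma": 0.7,
    "beta": 1.0,        # example-bout softmax (the smaller tree uses beta = 2)
    "xi": 0.0165,       # with gamma, jointly fixed by the canonical bout's
                        # characteristic five-update length
    "horizon": 3,
    "prior": ((1.0, 1.0), 0.51),   # {Beta(1,1), Known(0.51)}
}
MAZE_DEFAULTS = {
    "gamma": 0.9,
    "alpha": 0.6,
    "beta": 5.0,
    "phi": 5e-4,
    "xi": 0.02,
    "horizon": 8,
    "n_rollouts": 1000,
    "vi_tol": 1e-5,
}


@dataclass
class RunBundle:
    """Everything a scenario produced: summary metrics plus tidy tables."""

    scenario: str
    seed: int
    config: dict
    metrics: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "scenario": self.scenario,
            "seed": self.seed,
            "config": _jsonable(self.config),
            "config_hash": hashlib.sha256(
                json.dumps(_jsonable(self.config), sort_keys=True).encode()
            ).hexdigest()[:16],
            "metrics": _jsonable(self.metrics),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def updates_frame(executed: list[rb.ExecutedUpdate], bout: int = 0) -> pd.DataFrame:
    rows = [{
        "bout": bout, "step": u.step, "s_k": u.s_k, "a_k": u.a_k,
        "belief_key": str(u.belief_label), "gain": u.gain, "need": u.need,
        "evb": u.evb, "is_sequence": u.is_sequence, "seq_id": u.seq_id,
        "seq_pos": u.seq_pos, "seq_len": u.seq_len, "direction": u.direction,
    } for u in executed]
    return pd.DataFrame(rows, columns=[
        "bout", "step", "s_k", "a_k", "belief_key", "gain", "need", "evb",
        "is_sequence", "seq_id", "seq_pos", "seq_len", "direction"])


def _bandit_prior(prior) -> BanditBeliefState:
    arms = []
    for p in prior:
        if isinstance(p, (tuple, list)):
            arms.append(BetaBelief(*p))
        else:
            arms.append(KnownPayoff(float(p)))
    return BanditBeliefState(tuple(arms))


# ---------------------------------------------------------------------------
# bandit scenarios
# ---------------------------------------------------------------------------


def fig1_bandit_h2(seed: int = 0, **over) -> RunBundle:
    """Horizon-2 planning tree: exploratory vs certainty-equivalent Gain."""
    cfg = {**BANDIT_DEFAULTS, "horizon": 2, "beta": 2.0, **over}
    prior = _bandit_prior(cfg["prior"])
    tree = bandit_mod.build_tree(prior, cfg["horizon"], cfg["gamma"])
    bo = bandit_mod.bayes_optimal_values(tree)["root_value"]
    ce = bandit_mod.certainty_equivalent_values(
        prior, cfg["horizon"], cfg["gamma"])["root_value"]
    # exploratory Gain at the root, with the deeper tree already evaluated:
    # the potential replay update carries the propagated exploratory value
    root_q = tree.root.q_mb.copy()
    tree.root.q_mb[:] = 0.0
    eng = rb.BanditBeliefReplay(tree, cfg["beta"], cfg["xi"])
    need = eng.compute_need()
    gains = {}
    for a in range(prior.n_arms):
        _, per, _ = eng.evaluate_elements([rb.TreeElement(tree.root.index, a)], need)
        gains[f"root_gain_arm{a + 1}"] = per[0][1]
    tree.root.q_mb[:] = root_q
    metrics = {"bo_root_value": bo, "ce_root_value": ce, **gains,
               "n_nodes": len(tree.nodes)}
    edges = pd.DataFrame(tree.export_edges(), columns=[
        "parent_key", "action", "child_key", "prob", "reward", "depth"])
    edges["parent_key"] = edges["parent_key"].astype(str)
    edges["child_key"] = edges["child_key"].astype(str)
    return RunBundle("fig1_bandit_h2", seed, cfg, metrics, {"edges": edges})


def fig2_bandit_h3(seed: int = 0, sequences: bool = False, **over) -> RunBundle:
    """The canonical exploratory-replay bout in the horizon-3 belief tree."""
    cfg = {**BANDIT_DEFAULTS, **over}
    prior = _bandit_prior(cfg["prior"])
    tree = bandit_mod.build_tree(prior, cfg["horizon"], cfg["gamma"])
    bo = bandit_mod.bayes_optimal_values(tree)["root_value"]
    ce = bandit_mod.certainty_equivalent_values(
        prior, cfg["horizon"], cfg["gamma"])["root_value"]
    tree.reset_values()
    eng = rb.BanditBeliefReplay(tree, cfg["beta"], cfg["xi"])
    executed = eng.run(sequences=sequences,
                       max_length=cfg["horizon"] if sequences else None)
    metrics = {
        "n_updates": len(executed),
        "root_greedy_value": eng.root_greedy_value(),
        "evaluated_policy_value": eng.evaluated_policy_value(),
        "bo_root_value": bo,
        "ce_root_value": ce,
        "root_greedy_arm": int(tree.root.q_mb.argmax()) + 1,
    }
    return RunBundle("fig2_bandit_h3", seed, cfg, metrics,
                     {"replay": updates_frame(executed)})


def sweep(xi_grid, horizons=(2, 3), betas=(1.0,), seed: int = 0,
          prior=None, gamma: float | None = None) -> pd.DataFrame:
    """Tidy long-format table over (xi, horizon, beta): update counts, root
    value, evaluated-policy value and the BO/CE reference values."""
    gamma = BANDIT_DEFAULTS["gamma"] if gamma is None else gamma
    prior = _bandit_prior(prior or BANDIT_DEFAULTS["prior"])
    rows = []
    for h in horizons:
        tree = bandit_mod.build_tree(prior, h, gamma)
        bo = bandit_mod.bayes_optimal_values(tree)["root_value"]
        ce = bandit_mod.certainty_equivalent_values(prior, h, gamma)["root_value"]
        for beta in betas:
            for xi in xi_grid:
                tree.reset_values()
                eng = rb.BanditBeliefReplay(tree, beta, xi)
                executed = eng.run()
                rows.append({
                    "xi": xi, "horizon": h, "beta": beta, "seed": seed,
                    "n_updates": len(executed),
                    "root_value": eng.root_greedy_value(),
                    "policy_value": eng.evaluated_policy_value(),
                    "bo_value": bo, "ce_value": ce,
                })
    return pd.DataFrame(rows)


def supp_two_unknown_arms(seed: int = 0, n_seeds: int = 20, **over) -> RunBundle:
    """Sequence-replay protocol in value-shuffled both-arms-unknown trees.

    For each sub-seed, exact fixed-horizon values are computed by backward
    induction and shuffled across the tree's internal action slots; replay
    with sequences (max length = horizon) is compared against single-action
    replay.  Reports forward/reverse sequence fractions and updated-action
    counts.
    """
    cfg = {**BANDIT_DEFAULTS, "beta": 2.0, "xi": 0.005,
           "prior": ((13.0, 12.0), (2.0, 2.0)), **over}
    prior = _bandit_prior(cfg["prior"])
    ss = np.random.SeedSequence([seed, 20240501])
    frames = []
    n_fwd = n_rev = 0
    seq_actions, single_actions = [], []
    for i, child in enumerate(ss.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        base = bandit_mod.build_tree(prior, cfg["horizon"], cfg["gamma"])
        bandit_mod.bayes_optimal_values(base)
        shuffled = rng.permutation(
            np.concatenate([n.q_mb for n in base.internal_nodes()]))
        for mode in ("sequence", "single"):
            # identical shuffled initial values for both replay mechanisms
            tree = bandit_mod.build_tree(prior, cfg["horizon"], cfg["gamma"])
            internal = tree.internal_nodes()
            k = 0
            for n in internal:
                n.q_mb[:] = shuffled[k:k + n.state.n_arms]
                k += n.state.n_arms
            eng = rb.BanditBeliefReplay(tree, cfg["beta"], cfg["xi"])
            executed = eng.run(sequences=(mode == "sequence"),
                               max_length=cfg["horizon"])
            df = updates_frame(executed, bout=i)
            df["mode"] = mode
            frames.append(df)
            if mode == "sequence":
                if len(df) and df.is_sequence.any():
                    seqs = (df[df.is_sequence]
                            .groupby("seq_id")["direction"].first())
                    n_fwd += int((seqs == "forward").sum())
                    n_rev += int((seqs == "reverse").sum())
                seq_actions.append(len(df))
            else:
                single_actions.append(len(df))
    total = n_fwd + n_rev
    metrics = {
        "n_seeds": n_seeds,
        "n_forward_sequences": n_fwd,
        "n_reverse_sequences": n_rev,
        "forward_fraction": n_fwd / total if total else float("nan"),
        "reverse_fraction": n_rev / total if total else float("nan"),
        "mean_updated_actions_sequence": float(np.mean(seq_actions)),
        "mean_updated_actions_single": float(np.mean(single_actions)),
    }
    frames = [f for f in frames if len(f)] or frames[:1]
    return RunBundle("supp_two_unknown_arms", seed, cfg, metrics,
                     {"replay": pd.concat(frames, ignore_index=True)})


def sequence_direction_stats(log: pd.DataFrame) -> dict:
    """Forward/reverse fractions over sequence events plus updated-action
    counts; fractions are reported absent for a log without sequences."""
    seq = log[log["is_sequence"]]
    out = {"n_updated_actions": int(len(log))}
    if seq.empty:
        out.update({"forward_fraction": None, "reverse_fraction": None,
                    "n_sequences": 0})
        return out
    dirs = seq.groupby("seq_id")["direction"].first()
    n = len(dirs)
    out.update({
        "n_sequences": int(n),
        "forward_fraction": float((dirs == "forward").sum() / n),
        "reverse_fraction": float((dirs == "reverse").sum() / n),
    })
    return out


# ---------------------------------------------------------------------------
# maze scenarios
# ---------------------------------------------------------------------------


def _phase(agent: AgentState, spec, moves: int, xi: float,
           rng: np.random.Generator) -> dict:
    """One continual online phase: softmax behaviour over the legal moves,
    Q-learning, transition learning at barrier attempts, forgetting after
    every move, and known-environment prioritised replay after every move."""
    S = spec.n_states
    occupancy = np.zeros(S)
    total_reward = 0.0
    n_replay = 0
    s = spec.start
    for _ in range(moves):
        legal = maze_mod.legal_actions(spec, s)
        pi = softmax_policy(agent.q_mf[s, legal], agent.beta)
        a = int(legal[rng.choice(len(pi), p=pi)])
        s2, r = maze_mod.step(s, a, spec)
        hit = spec.barrier_on(s, a)
        if hit is not None and hit[1]:
            # barrier attempts teach the transition model what actually happened
            agent_mod.update_transition_model(agent, s, a, s2)
        agent_mod.q_learning_update(agent, s, a, r, s2)
        agent_mod.remember(agent, s, a, r, s2)
        agent_mod.forget(agent)
        n_replay += len(replay_md.replay_loop(agent, s2, xi))
        total_reward += r
        occupancy[s2] += 1
        s = s2
    return {"occupancy": occupancy / moves, "reward_rate": total_reward / moves,
            "n_replay_updates": n_replay}


def fig3_baseline_tolman(seed: int = 0, moves: int = 2000,
                         repeats: int = 10, **over) -> RunBundle:
    """Exploitative (certainty-assuming) replay agent before/after the top
    barrier is removed; the opened shortcut goes undiscovered."""
    cfg = {**MAZE_DEFAULTS, "beta": 20.0, "moves": moves, "repeats": repeats,
           **over}
    # phase 1: only the central corridor's exit is blocked (left route open)
    spec1 = tolman_maze(top_open=False, left_open=True)
    spec2 = maze_mod.with_barrier_open(spec1, 0, True)
    corridor = maze_mod.tolman_central_corridor(spec1)
    ss = np.random.SeedSequence([seed, 3])
    occ1 = np.zeros(spec1.n_states)
    occ2 = np.zeros(spec1.n_states)
    rr1 = rr2 = 0.0
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        agent = AgentState.for_maze(spec1, cfg["alpha"], cfg["beta"],
                                    cfg["gamma"], cfg["phi"])
        p1 = _phase(agent, spec1, moves, cfg["xi"], rng)
        p2 = _phase(agent, spec2, moves, cfg["xi"], rng)
        occ1 += p1["occupancy"] / repeats
        occ2 += p2["occupancy"] / repeats
        rr1 += p1["reward_rate"] / repeats
        rr2 += p2["reward_rate"] / repeats
    shortest = 6  # moves per lap through the opened shortcut
    metrics = {
        "phase1_reward_rate": rr1,
        "phase2_reward_rate": rr2,
        "optimal_phase2_reward_rate": 1.0 / shortest,
        "phase1_corridor_occupancy": float(occ1[corridor].sum()),
        "phase2_corridor_occupancy": float(occ2[corridor].sum()),
    }
    occ = pd.DataFrame({"state": np.arange(spec1.n_states),
                        "phase1": occ1, "phase2": occ2})
    return RunBundle("fig3_baseline_tolman", seed, cfg, metrics,
                     {"occupancy": occ})


def _fig5_engine(spec, q0, prior_entry, seed, cfg, root_state=None,
                 sequences=False, L=None):
    root = MazeBeliefState(root_state if root_state is not None else spec.start,
                           (prior_entry, RESOLVED_CLOSED))
    eng = rb.MazeBeliefReplay(
        spec, root, q0, cfg["gamma"], cfg["beta"], cfg["xi"], cfg["horizon"],
        n_rollouts=cfg["n_rollouts"], seed=np.random.SeedSequence([seed, 5]))
    executed = eng.run(sequences=sequences, max_length=L)
    return eng, executed


def fig5_exploratory(seed: int = 0, prior=(7.0, 2.0), sequences: bool = False,
                     discovery: bool = True, **over) -> RunBundle:
    """Exploratory replay with an uncertain shortcut barrier, then (optionally)
    the unlucky online discovery that the barrier is present.

    ``sequences=True`` turns this into the sequence-replay variant; the
    maximal length is the start-to-barrier action chain (5 elements).
    """
    cfg = {**MAZE_DEFAULTS, "prior": tuple(prior), "sequences": sequences, **over}
    spec = tolman_maze(top_open=False, left_open=False)
    P, R = maze_mod.true_transition_model(spec)
    q0 = value_iteration(P, R, cfg["gamma"], tol=cfg["vi_tol"])
    chain_states = [spec.start] + maze_mod.tolman_central_corridor(spec)
    L = len(chain_states) if sequences else None

    eng, executed = _fig5_engine(spec, q0, BetaBelief(*cfg["prior"]), seed, cfg,
                                 sequences=sequences, L=L)
    q_new = eng.write_back()
    start_greedy = int(q_new[spec.start].argmax())
    metrics = {
        "n_updates_exploratory": len(executed),
        "start_greedy_action": start_greedy,
        "start_points_to_barrier": bool(start_greedy == int(Action.UP)),
        "chain_q_up_before": [float(q0[s, Action.UP]) for s in chain_states],
        "chain_q_up_after": [float(q_new[s, Action.UP]) for s in chain_states],
    }
    tables = {"replay_exploratory": updates_frame(executed)}

    if discovery:
        barrier_state = chain_states[-1]
        q_disc = q_new.copy()
        q_disc[barrier_state, Action.UP] = 0.0
        eng2, executed2 = _fig5_engine(
            spec, q_disc, RESOLVED_CLOSED, seed + 1, cfg,
            root_state=barrier_state, sequences=sequences, L=L)
        q_final = eng2.write_back()
        tol = 10 * cfg["vi_tol"]  # value-iteration residual scale
        inflated = [s for s in chain_states
                    if q_final[s, Action.UP] > q0[s, Action.UP] + tol]
        metrics.update({
            "n_updates_discovery": len(executed2),
            "chain_q_up_final": [float(q_final[s, Action.UP])
                                 for s in chain_states],
            "n_inflated_chain_states": len(inflated),
            "inflated_chain_states": inflated,
        })
        tables["replay_discovery"] = updates_frame(executed2, bout=1)
    return RunBundle("fig5_exploratory", seed, cfg, metrics, tables)


def fig6_sequence(seed: int = 0, **over) -> RunBundle:
    """Fig-5 protocol with sequence replay enabled (deep value propagation)."""
    bundle = fig5_exploratory(seed, sequences=True, **over)
    return RunBundle("fig6_sequence", seed, bundle.config, bundle.metrics,
                     bundle.tables)


def fig4_single_barrier_tree(seed: int = 0, prior=(7.0, 2.0), **over) -> RunBundle:
    """Planning-tree snippet at the uncertain barrier: children probabilities
    and exploratory Gain for the attempt-to-cross versus retreat actions."""
    cfg = {**MAZE_DEFAULTS, "prior": tuple(prior), **over}
    spec = tolman_maze(top_open=False, left_open=False)
    P, R = maze_mod.true_transition_model(spec)
    q0 = value_iteration(P, R, cfg["gamma"], tol=cfg["vi_tol"])
    barrier_state = maze_mod.tolman_central_corridor(spec)[-1]
    root = MazeBeliefState(barrier_state, (BetaBelief(*cfg["prior"]),
                                           RESOLVED_CLOSED))
    eng = rb.MazeBeliefReplay(
        spec, root, q0, cfg["gamma"], cfg["beta"], cfg["xi"], 2,
        n_rollouts=cfg["n_rollouts"], seed=np.random.SeedSequence([seed, 4]))
    need = eng.compute_need()
    kids = eng.children(barrier_state, eng.root_ci, int(Action.UP))
    gains = {}
    for a in (Action.UP, Action.DOWN):
        cand = eng.candidate_of(rb.MazeElement(barrier_state, eng.root_ci, int(a)))
        evb, details = eng.eval_candidate(cand, need)
        own = next(d for d in details if d[0] == eng.root_ci)
        gains[f"gain_{Action(a).name.lower()}"] = own[1]
        gains[f"evb_{Action(a).name.lower()}"] = evb
    metrics = {
        "p_open_child": float(kids[0][2]),
        "p_closed_child": float(kids[1][2]),
        **gains,
    }
    return RunBundle("fig4_single_barrier_tree", seed, cfg, metrics)


def fig7_corridor(seed: int = 0, priors=((7.0, 2.0), (7.0, 2.0)),
                  **over) -> RunBundle:
    """Blocked central corridor with uncertain barriers at both ends (bottom
    one bidirectional); sequence replay in not-yet-visited belief states."""
    cfg = {**MAZE_DEFAULTS, "priors": tuple(map(tuple, priors)), **over}
    spec = tolman_maze(top_open=False, left_open=False,
                       with_bottom_barrier=True, bidirectional_bottom=True)
    P, R = maze_mod.true_transition_model(spec)
    q0 = value_iteration(P, R, cfg["gamma"], tol=cfg["vi_tol"])
    corridor = maze_mod.tolman_central_corridor(spec)
    q0 = q0.copy()
    q0[corridor] = 0.0  # inexperience with the blocked segment
    root = MazeBeliefState(spec.start, (
        BetaBelief(*cfg["priors"][0]), RESOLVED_CLOSED,
        BetaBelief(*cfg["priors"][1])))
    eng = rb.MazeBeliefReplay(
        spec, root, q0, cfg["gamma"], cfg["beta"], cfg["xi"], cfg["horizon"],
        n_rollouts=cfg["n_rollouts"], seed=np.random.SeedSequence([seed, 7]))
    executed = eng.run(sequences=True, max_length=len(corridor) + 2)
    df = updates_frame(executed)
    other_belief = df[df["belief_key"] != str(eng.element_label(
        rb.MazeElement(spec.start, eng.root_ci, 0)))]
    metrics = {
        "n_updates": len(executed),
        "n_corridor_updates": int(df["s_k"].isin(corridor).sum()),
        "n_updates_other_belief_states": int(len(other_belief)),
        "n_sequences": int(df[df.is_sequence]["seq_id"].nunique()),
    }
    return RunBundle("fig7_corridor", seed, cfg, metrics, {"replay": df})


def fig7d_tmaze(seed: int = 0, prior=(1.0, 1.0), **over) -> RunBundle:
    """Rest replay in the T-maze with a see-through barrier: no side-arm
    replay before cueing; replay confined to the cued arm afterwards."""
    cfg = {**MAZE_DEFAULTS, "horizon": 3, "prior": tuple(prior), **over}
    results = {}
    tables = {}
    for phase, cued in (("precue", False), ("postcue", True)):
        spec = tmaze(cued=cued)
        left, right = maze_mod.tmaze_arms(spec)
        stem_top = spec.cell(2, 2)
        root = MazeBeliefState(stem_top, (BetaBelief(*cfg["prior"]),))
        q0 = np.zeros((spec.n_states, len(maze_mod.ACTIONS)))
        eng = rb.MazeBeliefReplay(
            spec, root, q0, cfg["gamma"], cfg["beta"], cfg["xi"], cfg["horizon"],
            n_rollouts=cfg["n_rollouts"],
            seed=np.random.SeedSequence([seed, 77, int(cued)]))
        executed = eng.run(sequences=True, max_length=cfg["horizon"])
        df = updates_frame(executed)
        results[f"{phase}_updates"] = len(executed)
        results[f"{phase}_cued_arm_updates"] = int(df["s_k"].isin(right).sum())
        results[f"{phase}_uncued_arm_updates"] = int(df["s_k"].isin(left).sum())
        tables[f"replay_{phase}"] = df
    return RunBundle("fig7d_tmaze", seed, cfg, results, tables)


def supp_random_trees(seed: int = 0, n_inits: int = 50, **over) -> RunBundle:
    """Replay in value-shuffled trees: exact fixed-horizon values are computed
    by backward induction and randomly permuted across the internal action
    slots before replay runs; averages are reported over the shuffles."""
    cfg = {**BANDIT_DEFAULTS, "beta": 2.0, "xi": 0.005,
           "prior": ((13.0, 12.0), (2.0, 2.0)), **over}
    prior = _bandit_prior(cfg["prior"])
    ss = np.random.SeedSequence([seed, 20240502])
    counts, roots = [], []
    for child in ss.spawn(n_inits):
        rng = np.random.default_rng(child)
        tree = bandit_mod.build_tree(prior, cfg["horizon"], cfg["gamma"])
        bandit_mod.bayes_optimal_values(tree)
        internal = tree.internal_nodes()
        shuffled = rng.permutation(np.concatenate([n.q_mb for n in internal]))
        k = 0
        for n in internal:
            n.q_mb[:] = shuffled[k:k + n.state.n_arms]
            k += n.state.n_arms
        eng = rb.BanditBeliefReplay(tree, cfg["beta"], cfg["xi"])
        executed = eng.run(sequences=True, max_length=cfg["horizon"])
        counts.append(len(executed))
        roots.append(eng.root_greedy_value())
    metrics = {
        "n_inits": n_inits,
        "mean_updates": float(np.mean(counts)),
        "mean_root_value": float(np.mean(roots)),
        "sd_updates": float(np.std(counts)),
    }
    return RunBundle("supp_random_trees", seed, cfg, metrics)


def supp_prior_sweep(seed: int = 0,
                     priors=((7.0, 2.0), (2.0, 2.0), (2.0, 20.0)),
                     **over) -> RunBundle:
    """Exploration emergence as a function of the prior barrier belief."""
    rows = []
    for prior in priors:
        b = fig5_exploratory(seed, prior=prior, discovery=False, **over)
        rows.append({"prior_alpha": prior[0], "prior_beta": prior[1],
                     "p_open": prior[0] / (prior[0] + prior[1]),
                     "n_updates": b.metrics["n_updates_exploratory"],
                     "start_points_to_barrier":
                         b.metrics["start_points_to_barrier"]})
    df = pd.DataFrame(rows)
    metrics = {"n_priors": len(df),
               "explores_under_open_prior": bool(df.iloc[0]
                                                 .start_points_to_barrier)}
    return RunBundle("supp_prior_sweep", seed,
                     {**MAZE_DEFAULTS, **over}, metrics, {"sweep": df})


SCENARIOS = {
    "fig1_bandit_h2": fig1_bandit_h2,
    "fig2_bandit_h3": fig2_bandit_h3,
    "fig3_baseline_tolman": fig3_baseline_tolman,
    "fig4_single_barrier_tree": fig4_single_barrier_tree,
    "fig5_exploratory": fig5_exploratory,
    "fig6_sequence": fig6_sequence,
    "fig7_corridor": fig7_corridor,
    "fig7d_tmaze": fig7d_tmaze,
    "supp_two_unknown_arms": supp_two_unknown_arms,
    "supp_random_trees": supp_random_trees,
    "supp_prior_sweep": supp_prior_sweep,
}


def run_scenario(name: str, seed: int = 0, **overrides) -> RunBundle:
    """Dispatch a built-in scenario by name."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return SCENARIOS[name](seed=seed, **overrides)
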