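import numpy as np
import pytest

import beliefreplay as br
from beliefreplay import maze as mz
from beliefreplay.agent import softmax_policy
from beliefreplay.maze import Action
from beliefreplay.replay_belief import (BanditBeliefReplay, MazeBeliefReplay,
                                        MazeElement, children_of, mc_need)
from beliefreplay.replay_md import need_md, policy_transition_operator

from conftest import random_two_arm_prior


@pytest.fixture
def fig_engine(tolman, tolman_q0):
    root = br.MazeBeliefState(tolman.start,
                              (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
    return MazeBeliefReplay(tolman, root, tolman_q0, gamma=0.9, beta=5.0,
                            xi=0.02, horizon=8, n_rollouts=1000, seed=1)


class TestChildren:
    def test_uncertain_barrier_forks_with_predictive_probability(self, tolman):
        b = br.MazeBeliefState(tolman.cell(4, 2),
                               (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
        kids = children_of(tolman, b, Action.UP)
        (b_open, p_open, _), (b_closed, p_closed, _) = kids
        assert p_open == pytest.approx(7 / 9)
        assert p_closed == pytest.approx(2 / 9)
        assert b_open.s == tolman.cell(5, 2)
        assert b_open.barrier_beliefs[0] == br.RESOLVED_OPEN
        assert b_closed.s == b.s  # the failed attempt does not move the agent
        assert b_closed.barrier_beliefs[0] == br.RESOLVED_CLOSED

    def test_resolved_closed_barrier_self_loops(self, tolman):
        b = br.MazeBeliefState(tolman.cell(4, 2),
                               (br.RESOLVED_CLOSED, br.RESOLVED_CLOSED))
        kids = children_of(tolman, b, Action.UP)
        assert kids == [(b, 1.0, 0.0)]

    def test_plain_corridor_move_keeps_the_belief(self, tolman):
        b = br.MazeBeliefState(tolman.cell(1, 2),
                               (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
        kids = children_of(tolman, b, Action.UP)
        assert kids == [(b.with_state(tolman.cell(2, 2)), 1.0, 0.0)]

    def test_probabilities_sum_to_one_everywhere(self, fig_engine):
        for s, ci in fig_engine.disc:
            for a in mz.ACTIONS:
                kids = fig_engine.children(s, ci, a)
                assert sum(p for _, _, p, _ in kids) == pytest.approx(1.0)


class TestBeliefBackup:
    def test_fork_backup_arithmetic_oracle(self, fig_engine, tolman, tolman_q0):
        """Q = (7/9)(r_o + g V_open) + (2/9)(r_c + g V_closed), by hand."""
        s = tolman.cell(4, 2)
        v = fig_engine.backup(s, fig_engine.root_ci, int(Action.UP))
        ci_open = fig_engine.ci_of[(br.RESOLVED_OPEN, br.RESOLVED_CLOSED)]
        ci_closed = fig_engine.ci_of[(br.RESOLVED_CLOSED, br.RESOLVED_CLOSED)]
        v_open = fig_engine.q_row(tolman.cell(5, 2), ci_open).max()
        v_closed = fig_engine.q_row(s, ci_closed).max()
        assert v == pytest.approx((7 / 9) * 0.9 * v_open + (2 / 9) * 0.9 * v_closed)

    def test_consistent_entry_is_a_fixed_point(self, fig_engine, tolman):
        s = tolman.cell(1, 2)
        v = fig_engine.backup(s, fig_engine.root_ci, int(Action.UP))
        fig_engine.q_row(s, fig_engine.root_ci)[int(Action.UP)] = v
        assert fig_engine.backup(s, fig_engine.root_ci, int(Action.UP)) == \
            pytest.approx(v)

    def test_resolved_beliefs_reduce_to_physical_bellman_backup(
            self, tolman, tolman_q0):
        """With every barrier resolved, the belief backup equals the ordinary
        one-step backup on the physical MDP."""
        root = br.MazeBeliefState(tolman.start,
                                  (br.RESOLVED_CLOSED, br.RESOLVED_CLOSED))
        eng = MazeBeliefReplay(tolman, root, tolman_q0, 0.9, 5.0, 0.02, 8,
                               n_rollouts=100, seed=0)
        P, R = mz.true_transition_model(tolman)
        for s in eng.disc_states:
            for a in mz.ACTIONS:
                expected = R[s, a] + 0.9 * (P[s, a] @ tolman_q0.max(axis=1))
                assert eng.backup(s, 0, int(a)) == pytest.approx(expected)

    def test_public_belief_backup_helper(self, tolman, tolman_q0):
        b = br.MazeBeliefState(tolman.cell(4, 2),
                               (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
        kids = children_of(tolman, b, Action.UP)
        v = br.belief_backup(lambda bc: tolman_q0[bc.s], kids, 0.9)
        v_open = tolman_q0[tolman.cell(5, 2)].max()
        v_closed = tolman_q0[b.s].max()
        assert v == pytest.approx(0.9 * ((7 / 9) * v_open + (2 / 9) * v_closed))


class TestGainBelief:
    def test_no_change_no_gain(self):
        q = np.array([0.4, 0.2, 0.1, 0.1])
        assert br.gain_belief(q, 0, 0.4, 5.0) == pytest.approx(0.0)

    def test_uniform_policies_have_zero_gain(self):
        q = np.array([0.4, 0.2, 0.1, 0.1])
        assert br.gain_belief(q, 0, 2.0, 0.0) == pytest.approx(0.0)

    def test_two_action_flip_matches_policy_difference(self):
        q = np.array([0.2, 0.5])
        g = br.gain_belief(q, 0, 1.0, 3.0)
        q_new = np.array([1.0, 0.5])
        po, pn = softmax_policy(q, 3.0), softmax_policy(q_new, 3.0)
        assert g == pytest.approx(float((pn - po) @ q_new))


class TestMcNeed:
    def five_state_setup(self, beta=2.0, gamma=0.9):
        spec = mz.MazeSpec(width=5, height=1, start=0, goal=4)
        P, R = mz.true_transition_model(spec)
        Q = mz.value_iteration(P, R, gamma)
        return spec, P, Q

    def test_matches_resolvent_with_no_uncertainty(self):
        """No uncertain barriers: the Monte-Carlo estimate agrees with the
        closed-form discounted successor representation within 3 SE."""
        beta, gamma = 2.0, 0.9
        spec, P, Q = self.five_state_setup(beta, gamma)
        root = br.MazeBeliefState(0, ())
        nm = mc_need(spec, root, [()], Q[None], beta, gamma, 10_000,
                     np.random.default_rng(5))
        pi = softmax_policy(Q, beta)
        exact = need_md(policy_transition_operator(P, pi), 0, gamma)
        M = np.linalg.inv(np.eye(5) - gamma * policy_transition_operator(P, pi))
        for s in range(5):
            m1 = nm.first_hit_discount[(s, 0)]
            m2 = nm.first_hit_discount_sq[(s, 0)]
            se = np.sqrt(max(m2 - m1 ** 2, 0) / nm.n_rollouts) * M[s, s]
            assert abs(nm.need[(s, 0)] - exact[s]) <= max(3 * se, 1e-12)

    def test_root_need_at_least_one(self, fig_engine):
        for seed in (0, 1, 2):
            fig_engine._ss = np.random.SeedSequence(seed)
            nm = fig_engine.compute_need()
            assert nm[(fig_engine.root.s, fig_engine.root_ci)] >= 1.0

    def test_first_hit_term_unbiased_on_enumerable_toy(self):
        """Mean gamma^K matches exhaustive path enumeration on a 2-state toy
        within 3 SE."""
        spec = mz.MazeSpec(width=2, height=1, start=0, goal=None)
        Q = np.zeros((2, 4))
        gamma, beta = 0.5, 0.0  # uniform policy, fast truncation
        root = br.MazeBeliefState(0, ())
        nm = mc_need(spec, root, [()], Q[None], beta, gamma, 20_000,
                     np.random.default_rng(9))
        # uniform over 4 actions: P(move right)=1/4, stay 3/4
        # K(state 1) geometric: P(K=k) = (3/4)^{k-1} (1/4), within truncation
        d_max = int(np.floor(np.log(1e-5) / np.log(gamma)))
        exact = sum((3 / 4) ** (k - 1) * (1 / 4) * gamma ** k
                    for k in range(1, d_max + 1))
        m1 = nm.first_hit_discount[(1, 0)]
        m2 = nm.first_hit_discount_sq[(1, 0)]
        se = np.sqrt((m2 - m1 ** 2) / nm.n_rollouts)
        assert abs(m1 - exact) <= 3 * se

    def test_trajectory_length_respects_discount_truncation(self):
        """gamma^d <= eps stops a trajectory: no first hit can occur later
        than floor(log eps / log gamma)."""
        spec = mz.MazeSpec(width=5, height=1, start=0, goal=None)
        Q = np.zeros((5, 4))
        gamma, eps = 0.8, 1e-3
        nm = mc_need(spec, br.MazeBeliefState(0, ()), [()], Q[None], 0.0,
                     gamma, 2000, np.random.default_rng(0), eps=eps)
        d_max = int(np.floor(np.log(eps) / np.log(gamma)))
        for key, frac in nm.hit_fraction.items():
            if frac > 0:
                assert nm.first_hit_discount[key] >= frac * gamma ** d_max

    def test_series_tail_variant_runs(self):
        spec, P, Q = self.five_state_setup()
        nm = mc_need(spec, br.MazeBeliefState(0, ()), [()], Q[None], 2.0, 0.9,
                     500, np.random.default_rng(1), tail="series")
        assert nm.need[(0, 0)] >= 1.0

    def test_invalid_arguments_rejected(self):
        spec, P, Q = self.five_state_setup()
        with pytest.raises(ValueError):
            mc_need(spec, br.MazeBeliefState(0, ()), [()], Q[None], 2.0, 0.9,
                    0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            mc_need(spec, br.MazeBeliefState(0, ()), [()], Q[None], 2.0, 0.9,
                    10, np.random.default_rng(0), tail="bogus")


class TestEvb:
    def test_candidate_changing_nothing_has_zero_evb(self, fig_engine, tolman):
        s = tolman.cell(1, 2)
        need = fig_engine.compute_need()
        # make the entry Bellman-consistent in every affected combination
        cand = fig_engine.candidate_of(
            MazeElement(s, fig_engine.root_ci, int(Action.UP)))
        for ci in fig_engine.affected_configs(cand):
            fig_engine.q_row(s, ci)[int(Action.UP)] = \
                fig_engine.backup(s, ci, int(Action.UP))
        evb, _ = fig_engine.eval_candidate(cand, need)
        assert evb == pytest.approx(0.0, abs=1e-12)

    def test_generalised_evb_is_need_weighted_sum_of_gains(self, fig_engine,
                                                           tolman):
        """The outer sum over beliefs: EVB equals the sum of Need x Gain over
        the affected belief states, each with its own backup (verified term by
        term)."""
        s = tolman.cell(2, 2)
        need = fig_engine.compute_need()
        cand = fig_engine.candidate_of(
            MazeElement(s, fig_engine.root_ci, int(Action.UP)))
        evb, details = fig_engine.eval_candidate(cand, need)
        manual = 0.0
        for ci, g, v in details:
            row = fig_engine.q_row(s, ci)
            assert v == pytest.approx(fig_engine.backup(s, ci, int(Action.UP)))
            assert g == pytest.approx(br.gain_belief(row, int(Action.UP), v, 5.0))
            manual += need[(s, ci)] * g
        assert evb == pytest.approx(manual)
        assert len(details) > 1  # the update really generalises

    def test_single_belief_effect_localises_to_need_times_gain(self, tolman,
                                                               tolman_q0):
        """With every barrier resolved there is one combination, and the
        belief-space EVB reduces to the known-environment Need x Gain form."""
        root = br.MazeBeliefState(tolman.start,
                                  (br.RESOLVED_CLOSED, br.RESOLVED_CLOSED))
        eng = MazeBeliefReplay(tolman, root, tolman_q0, 0.9, 5.0, 0.02, 8,
                               n_rollouts=2000, seed=3)
        need = eng.compute_need()
        s = tolman.cell(1, 2)
        cand = eng.candidate_of(MazeElement(s, 0, int(Action.DOWN)))
        evb, details = eng.eval_candidate(cand, need)
        (_, g, _), = details
        assert evb == pytest.approx(need[(s, 0)] * g)


class TestExploratoryReplayLoop:
    def test_huge_threshold_means_no_updates(self, tolman, tolman_q0):
        root = br.MazeBeliefState(tolman.start,
                                  (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
        eng = MazeBeliefReplay(tolman, root, tolman_q0, 0.9, 5.0, 1e9, 8,
                               n_rollouts=100, seed=0)
        executed, q_new = br.exploratory_replay_loop(eng)
        assert executed == []
        np.testing.assert_array_equal(q_new, tolman_q0)

    def test_reverse_chain_from_barrier_to_start(self, fig_engine, tolman,
                                                 corridor_chain):
        """The uncertain shortcut triggers consecutive reverse updates from
        the barrier to the agent, flipping the start policy toward it."""
        executed, q_new = br.exploratory_replay_loop(fig_engine)
        assert [(u.s_k, u.a_k) for u in executed] == \
            [(s, int(Action.UP)) for s in reversed(corridor_chain)]
        assert int(q_new[tolman.start].argmax()) == int(Action.UP)

    def test_strongly_closed_prior_does_not_recruit_exploration(
            self, tolman, tolman_q0):
        root = br.MazeBeliefState(tolman.start,
                                  (br.BetaBelief(2, 20), br.RESOLVED_CLOSED))
        eng = MazeBeliefReplay(tolman, root, tolman_q0, 0.9, 5.0, 0.02, 8,
                               n_rollouts=1000, seed=1)
        _, q_new = br.exploratory_replay_loop(eng)
        assert int(q_new[tolman.start].argmax()) != int(Action.UP)

    def test_writeback_only_touches_root_belief_updates(self, fig_engine,
                                                        tolman, tolman_q0):
        executed, q_new = br.exploratory_replay_loop(fig_engine)
        changed = {(s, a) for s in range(tolman.n_states)
                   for a in range(4) if q_new[s, a] != tolman_q0[s, a]}
        executed_pairs = {(u.s_k, u.a_k) for u in executed}
        assert changed <= executed_pairs


class TestBanditReplayConvergence:
    def test_replay_to_convergence_equals_backward_induction(self):
        """xi -> 0 replay reaches the full-DP root value and policy value for
        any bandit tree with horizon <= 4 (oracle equivalence)."""
        rng = np.random.default_rng(21)
        for h in (2, 3, 4):
            for _ in range(5):
                prior = random_two_arm_prior(rng)
                tree = br.build_tree(prior, h, 0.9)
                bo = br.bayes_optimal_values(tree)["root_value"]
                tree.reset_values()
                eng = BanditBeliefReplay(tree, beta=1.0, xi=1e-12)
                eng.run()
                assert eng.root_greedy_value() == pytest.approx(bo, abs=1e-6)
                assert eng.evaluated_policy_value() == pytest.approx(bo, abs=1e-6)

    def test_update_count_nonincreasing_in_xi(self, canonical_prior):
        counts = []
        for xi in np.geomspace(1e-6, 3.0, 10):
            tree = br.build_tree(canonical_prior, 3, 0.7)
            eng = BanditBeliefReplay(tree, beta=1.0, xi=float(xi))
            counts.append(len(eng.run()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[0] > 0 and counts[-1] == 0
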