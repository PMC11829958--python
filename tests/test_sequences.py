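import numpy as np
import pytest

import beliefreplay as br
from beliefreplay import maze as mz
from beliefreplay.maze import Action
from beliefreplay.replay_belief import (BanditBeliefReplay, MazeBeliefReplay,
                                        MazeElement, TreeElement)
from beliefreplay.sequences import (ReplaySequence, apply_sequence,
                                    generate_sequences, sequence_evb)


@pytest.fixture
def tree_engine(canonical_prior):
    tree = br.build_tree(canonical_prior, 3, 0.7)
    return BanditBeliefReplay(tree, beta=1.0, xi=1e-4)


@pytest.fixture
def maze_engine(tolman, tolman_q0):
    root = br.MazeBeliefState(tolman.start,
                              (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
    return MazeBeliefReplay(tolman, root, tolman_q0, gamma=0.9, beta=5.0,
                            xi=0.02, horizon=8, n_rollouts=1000, seed=1)


class TestGeneration:
    def test_singles_are_not_sequences(self, tree_engine):
        need = tree_engine.compute_need()
        seqs = generate_sequences(tree_engine, need, 1, "reverse", 1e-9)
        assert seqs == []  # L=1: the single-action candidate set stands alone

    def test_no_physical_repeats(self, maze_engine):
        need = maze_engine.compute_need()
        for direction in ("forward", "reverse"):
            for seq in generate_sequences(maze_engine, need, 4, direction,
                                          1e-6, beam_width=32):
                states = [el.physical for el in seq.elements]
                assert len(states) == len(set(states))

    def test_all_surviving_sequences_clear_the_threshold(self, maze_engine):
        need = maze_engine.compute_need()
        xi = 0.01
        for seq in generate_sequences(maze_engine, need, 4, "reverse", xi,
                                      beam_width=32):
            assert seq.evb > xi

    def test_reverse_chain_links_consecutive_beliefs(self, maze_engine):
        """Each later element's action leads to the previous element's belief
        state (value propagates along the chain)."""
        need = maze_engine.compute_need()
        for seq in generate_sequences(maze_engine, need, 3, "reverse", 1e-6,
                                      beam_width=16):
            for earlier, later in zip(seq.elements, seq.elements[1:]):
                kids = maze_engine.children(later.s, later.ci, later.a)
                assert (earlier.s, earlier.ci) in {(s, c) for s, c, _, _ in kids}

    def test_barrier_to_start_chain_is_generated(self, maze_engine,
                                                 corridor_chain):
        """The reverse chain from the uncertain barrier down to the start
        survives generation when its far-sighted EVB clears the threshold."""
        need = maze_engine.compute_need()
        seed_f, emit_f = maze_engine.sequence_filters("reverse")
        seqs = generate_sequences(maze_engine, need, 5, "reverse",
                                  maze_engine.xi, seed_filter=seed_f,
                                  emit_filter=emit_f)
        wanted = [(s, int(Action.UP)) for s in reversed(corridor_chain)]
        assert any([(el.s, el.a) for el in seq.elements] == wanted
                   for seq in seqs)

    def test_invalid_direction_rejected(self, tree_engine):
        with pytest.raises(ValueError):
            generate_sequences(tree_engine, tree_engine.compute_need(), 2,
                               "sideways", 1e-4)


class TestSequenceEvb:
    def test_length_one_equals_single_candidate_evb(self, maze_engine):
        need = maze_engine.compute_need()
        for el in maze_engine.single_elements()[:40]:
            single, _, _ = maze_engine.evaluate_elements([el], need)
            seq = ReplaySequence((el,), "reverse", single, ())
            assert sequence_evb(maze_engine, seq, need) == single

    def test_reverse_chain_beats_best_single_on_deep_propagation(
            self, canonical_prior):
        """A two-element reverse chain through a freshly built tree carries
        value two steps in one event; its far-sighted EVB exceeds every
        myopic single-action EVB (exhaustive two-update oracle)."""
        tree = br.build_tree(canonical_prior, 3, 0.7)
        eng = BanditBeliefReplay(tree, beta=1.0, xi=1e-9)
        need = eng.compute_need()
        best_single = max(eng.evaluate_elements([el], need)[0]
                          for el in eng.single_elements())
        best_chain = max(
            (seq.evb for seq in generate_sequences(eng, need, 2, "reverse",
                                                   1e-12)),
            default=-np.inf)
        assert best_chain > best_single

    def test_consistent_values_give_zero_sequence_evb(self, canonical_prior):
        tree = br.build_tree(canonical_prior, 3, 0.7)
        br.bayes_optimal_values(tree)  # every entry Bellman-consistent
        eng = BanditBeliefReplay(tree, beta=1.0, xi=1e-9)
        need = eng.compute_need()
        for seq in generate_sequences(eng, need, 3, "reverse", -1.0)[:20]:
            assert seq.evb == pytest.approx(0.0, abs=1e-12)

    def test_forward_and_reverse_of_same_elements_differ(self, canonical_prior):
        """Exhaustive two-update evaluation: execution order changes the
        intermediate values, hence the far-sighted EVB."""
        tree = br.build_tree(canonical_prior, 3, 0.7)
        eng = BanditBeliefReplay(tree, beta=1.0, xi=1e-9)
        need = eng.compute_need()
        parent = tree.root
        child = parent.children[0][0][0]
        fwd = [TreeElement(parent.index, 0), TreeElement(child.index, 0)]
        rev = list(reversed(fwd))
        evb_f, _, _ = eng.evaluate_elements(fwd, need)
        evb_r, _, _ = eng.evaluate_elements(rev, need)
        assert evb_f != pytest.approx(evb_r, abs=1e-9)


class TestApplySequence:
    def test_commit_then_reevaluate_is_zero(self, maze_engine, corridor_chain):
        need = maze_engine.compute_need()
        wanted = [(s, int(Action.UP)) for s in reversed(corridor_chain)]
        seed_f, emit_f = maze_engine.sequence_filters("reverse")
        seqs = generate_sequences(maze_engine, need, 5, "reverse",
                                  maze_engine.xi, seed_filter=seed_f,
                                  emit_filter=emit_f)
        seq = next(s for s in seqs
                   if [(el.s, el.a) for el in s.elements] == wanted)
        apply_sequence(maze_engine, seq)
        assert sequence_evb(maze_engine, seq, need) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_discovered_closed_barrier_chain_decreases_everywhere(
            self, tolman, tolman_q0, corridor_chain):
        """After the barrier is found closed, committing the reverse chain
        lowers every previously boosted action value (sign check on the
        scripted discovery scenario)."""
        UP = int(Action.UP)
        root = br.MazeBeliefState(tolman.start,
                                  (br.BetaBelief(7, 2), br.RESOLVED_CLOSED))
        eng = MazeBeliefReplay(tolman, root, tolman_q0, 0.9, 5.0, 0.02, 8,
                               n_rollouts=1000, seed=1)
        eng.run()
        boosted = eng.write_back()
        barrier_state = corridor_chain[-1]
        q_disc = boosted.copy()
        q_disc[barrier_state, UP] = 0.0
        root2 = br.MazeBeliefState(barrier_state,
                                   (br.RESOLVED_CLOSED, br.RESOLVED_CLOSED))
        eng2 = MazeBeliefReplay(tolman, root2, q_disc, 0.9, 5.0, 0.02, 8,
                                n_rollouts=1000, seed=2)
        elements = [MazeElement(s, 0, UP) for s in reversed(corridor_chain)]
        need = eng2.compute_need()
        total, per, _ = eng2.evaluate_elements(elements, need)
        seq = ReplaySequence(tuple(elements), "reverse", total, tuple(per))
        apply_sequence(eng2, seq)
        q_final = eng2.write_back()
        for s in corridor_chain[:-1]:
            assert q_final[s, UP] < boosted[s, UP]
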