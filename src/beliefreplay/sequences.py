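"""Forward and reverse replay sequences with far-sighted EVB.

A sequence is an ordered candidate set M_N of (belief state, action) pairs
linked through the belief transition model.  Its elements are updated
*within one replay iteration* (fractional updates on a scratch copy), so for
reverse sequences each later element's backup consumes the already-updated
value of its child -- this is what lets bad (or good) news propagate deeply in
a single prioritised event.  The total EVB is the sum of the per-element EVBs
evaluated at the intermediate value state.

Generation follows three constraints: (i) physical states along a sequence
never repeat (no loops); (ii) an extension survives only if the extended
sequence's EVB exceeds the replay threshold xi; (iii) sequences stay inside
the discretised, horizon-limited belief space.  Reverse sequences step
backwards through the *forward* transition model (same uncertainty assigned
to reverse transitions); no separate inverse model is learned.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReplaySequence:
    elements: tuple              # execution order (first updated first)
    direction: str               # "forward" | "reverse"
    evb: float                   # far-sighted total
    per_element: tuple           # (evb_i, gain_i, new_value_i) per element

    def __len__(self) -> int:
        return len(self.elements)


def generate_sequences(engine, need, L: int, direction: str, xi: float,
                       beam_width: int | None = None,
                       seed_filter=None, emit_filter=None) -> list[ReplaySequence]:
    """Grow sequences of length 2..L from all single-action candidates.

    Forward sequences append successor elements (actions applied from the
    belief states the previous element can lead to); reverse sequences append
    predecessor elements (whose action leads to the previous element's belief
    state), so execution runs from the deep end back towards the agent.
    ``beam_width`` optionally caps the per-length frontier to the highest-EVB
    sequences, a computational cap for large discretisations.  ``seed_filter``
    restricts which elements may start a sequence and ``emit_filter`` which
    completed sequences are returned (both see the trajectory's elements);
    engines use them to anchor events at critical decision points.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if L < 1:
        raise ValueError("L must be >= 1")
    extend = (engine.element_successors if direction == "forward"
              else engine.element_predecessors)

    frontier: list[tuple[tuple, set]] = [
        ((el,), {el.physical}) for el in engine.single_elements()
        if seed_filter is None or seed_filter(el)
    ]
    out: list[ReplaySequence] = []
    for _ in range(1, L):
        nxt: list[tuple[tuple, set, ReplaySequence]] = []
        for elements, visited in frontier:
            for el in extend(elements[-1]):
                if el.physical in visited:  # constraint (i): no loops
                    continue
                seq_elements = elements + (el,)
                total, per, _ = engine.evaluate_elements(list(seq_elements), need)
                if total > xi:  # constraint (ii)
                    nxt.append((seq_elements, visited | {el.physical},
                                ReplaySequence(seq_elements, direction,
                                               total, tuple(per))))
        if beam_width is not None and len(nxt) > beam_width:
            nxt.sort(key=lambda t: -t[2].evb)
            nxt = nxt[:beam_width]
        out.extend(seq for _, _, seq in nxt
                   if emit_filter is None or emit_filter(seq.elements))
        frontier = [(elements, visited) for elements, visited, _ in nxt]
        if not frontier:
            break
    return out


def sequence_evb(engine, seq: ReplaySequence, need) -> float:
    """Far-sighted EVB of a sequence: fractional updates applied in order on a
    scratch copy, each element scored by its Eq.-style Need x Gain at the
    intermediate value state."""
    total, _, _ = engine.evaluate_elements(list(seq.elements), need)
    return total


def apply_sequence(engine, seq: ReplaySequence) -> list:
    """Commit the sequence's updates in order on the live value table; returns
    per-element (new value) log entries via the engine."""
    engine.apply_elements(list(seq.elements))
    return list(seq.elements)
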