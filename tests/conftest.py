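import numpy as np
import pytest

import beliefreplay as br
from beliefreplay import maze as mz


@pytest.fixture(scope="session")
def canonical_prior():
    """One unknown arm (flat prior), one known arm paying 0.51."""
    return br.BanditBeliefState((br.BetaBelief(1, 1), br.KnownPayoff(0.51)))


@pytest.fixture(scope="session")
def tolman():
    """Three-corridor detour maze with both barriers present."""
    return mz.tolman_maze(top_open=False, left_open=False)


@pytest.fixture(scope="session")
def tolman_q0(tolman):
    """Model-free values from value iteration under the all-closed truth."""
    P, R = mz.true_transition_model(tolman)
    return mz.value_iteration(P, R, 0.9)


@pytest.fixture(scope="session")
def corridor_chain(tolman):
    """Start state plus the central-corridor cells, bottom to top."""
    return [tolman.start] + mz.tolman_central_corridor(tolman)


def random_two_arm_prior(rng):
    """A value-of-information-bearing random prior.

    Integer Beta pseudo-counts in {1..3}; the known payoff sits strictly
    below the unknown arm's mean but above its worst horizon-4 posterior, so
    pulling the unknown arm is optimal yet its posterior can fall below the
    safe alternative -- information therefore has strictly positive value for
    every draw.
    """
    a, b = (int(x) for x in rng.integers(1, 4, 2))
    mean = a / (a + b)
    mu = float(mean - rng.uniform(0.01, 0.1))
    return br.BanditBeliefState((br.BetaBelief(a, b), br.KnownPayoff(mu)))
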