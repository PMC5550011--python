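import numpy as np
import pytest

import reachloss as rl


@pytest.fixture(scope="session")
def exp1_sr():
    return rl.make_exp1_prior("right")


@pytest.fixture(scope="session")
def exp1_sl():
    return rl.make_exp1_prior("left")


@pytest.fixture(scope="session")
def exp2_sr():
    return rl.make_exp2_prior("right")


@pytest.fixture(scope="session")
def exp2_sl():
    return rl.make_exp2_prior("left")


def random_discrete_distribution(rng, n_atoms=None):
    """A random strictly-increasing discrete distribution for property
    tests."""
    n = n_atoms or int(rng.integers(2, 9))
    support = np.sort(rng.uniform(-30, 30, size=n))
    while np.any(np.diff(support) < 1e-3):
        support = np.sort(rng.uniform(-30, 30, size=n))
    probs = rng.dirichlet(np.ones(n))
    return rl.ShiftDistribution(support, probs / probs.sum())
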