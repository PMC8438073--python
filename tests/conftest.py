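import warnings

import numpy as np
import pytest

from dendrocp import GroundTruth, generate_gradient, simulate_bai_series

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def child_seeds(entropy, n: int) -> list[int]:
    """Derive n independent sub-31-bit seeds from one master entropy value
    (an integer or a list of integers)."""
    ss = np.random.SeedSequence(entropy)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@pytest.fixture(scope="session")
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def gradient_small():
    return generate_gradient(20, 6, 0.06, 1.19, seed=10)


@pytest.fixture(scope="session")
def sim_small(gradient_small, truth):
    """A 20-tree, 12-year simulated growth study shared across tests."""
    return simulate_bai_series(gradient_small, None, truth, 12, seed=5)
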