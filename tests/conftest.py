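import numpy as np
import pytest

from mfikit import JointTable


def random_table(rng, arities, variables=None, positive=True):
    """A random strictly-positive joint table with the given arities."""
    probs = rng.random(tuple(arities))
    if positive:
        probs += 0.05  # keep states away from zero so logs stay finite
    probs /= probs.sum()
    if variables is None:
        variables = tuple(f"X{i}" for i in range(len(arities)))
    return JointTable(variables, probs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230412)


@pytest.fixture
def table3(rng):
    """A random positive 3-variable binary table with variables X, Y, Z."""
    return random_table(rng, (2, 2, 2), variables=("X", "Y", "Z"))
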