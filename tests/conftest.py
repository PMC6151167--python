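import numpy as np
import pytest


@pytest.fixture
def toy_populations():
    """Two populations of two 10-site haplotypes with hand-counted diffs.

    Within-pair differences: 1 (pop1) and 1 (pop2); between-population
    pair differences: 2, 3, 3, 2. Hence pi1 = pi2 = piS = 0.1,
    piT = 0.2, dXY = 0.25, FST = 0.5, da = 0.15.
    """
    pop1 = np.array([[0] * 10,
                     [0] * 9 + [1]], dtype=np.int8)
    pop2 = np.array([[1, 1] + [0] * 8,
                     [1, 1] + [0] * 7 + [1]], dtype=np.int8)
    return pop1, pop2


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
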