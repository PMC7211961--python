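import numpy as np
import pytest

import treeseg as ts


@pytest.fixture(scope="session")
def qtable_512():
    """Null quantile table for n<=512 analyses; shared across the suite."""
    return ts.simulate_M(grid_size=512, n_draws=5000, seed=101, min_scale=None)


@pytest.fixture(scope="session")
def qtable_small():
    """Coarse table for fast unit tests on tiny trees."""
    return ts.simulate_M(grid_size=128, n_draws=600, seed=7, min_scale=None)


@pytest.fixture
def balanced4():
    return ts.read_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar4():
    return ts.read_newick("(((A,B),C),D);")
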