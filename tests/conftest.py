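import numpy as np
import pytest

from eex.model import TimeGrid, make_simple_spec


@pytest.fixture(scope="session")
def log_grid_1e4():
    return TimeGrid(np.concatenate([[0.0], np.geomspace(1e-3, 1e4, 200)]))


@pytest.fixture(scope="session")
def two_type_spec():
    return make_simple_spec(2)


@pytest.fixture(scope="session")
def single_type_ensemble():
    """20k replicates of the single-type critical chain to t = 5."""
    from eex.simulator import ensemble

    grid = TimeGrid([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    return ensemble(make_simple_spec(1), grid, reps=20000, seed=424242, keep_counts=True)
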