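import numpy as np
import pytest

import colliscope as cs


@pytest.fixture(scope="session")
def tone_grid():
    return cs.build_tone_grid()


@pytest.fixture(scope="session")
def am_grid():
    return cs.build_am_grid()


@pytest.fixture(scope="session")
def small_experiment(tone_grid):
    """30 random-layout cells, 5 repeats of the tone grid, default noise."""
    cells = cs.generate_cells(30, layout="random", seed=11)
    schedule = cs.make_schedule(tone_grid, n_repeats=5, seed=12)
    return cs.simulate_traces(cells, schedule, seed=13)


@pytest.fixture(scope="session")
def small_analysis(small_experiment):
    dff = cs.process_experiment(small_experiment)
    return cs.analyze(dff, small_experiment.schedule)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
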