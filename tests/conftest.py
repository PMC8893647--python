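import numpy as np
import pytest

from cngrowth import GrowthMode, load_organism, simulate_generations


@pytest.fixture(scope="session")
def yeast():
    return load_organism("yeast")


@pytest.fixture(scope="session")
def mammalian():
    return load_organism("mammalian")


@pytest.fixture(scope="session")
def yeast_rich_traj(yeast):
    """One shared rich-medium yeast lineage (8 generations)."""
    return simulate_generations(yeast.initial_state, yeast.parameters,
                                GrowthMode.rich(), n_generations=8)


@pytest.fixture(scope="session")
def mammalian_rich_traj(mammalian):
    return simulate_generations(mammalian.initial_state,
                                mammalian.parameters,
                                GrowthMode.rich(), n_generations=8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
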