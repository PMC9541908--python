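import numpy as np
import pytest

from artmeta.effects import DirectionRule
from artmeta.simulate import SimulationConfig, simulate_effects, simulate_tree


@pytest.fixture(scope="session")
def rule():
    return DirectionRule("guarder", "sneaker")


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_tree):
    """~40 effects over 8 species; used wherever a quick realistic fit is needed."""
    cfg = SimulationConfig(seed=11, n_species=8, n_effects=40)
    return simulate_effects(cfg, small_tree)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
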