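import numpy as np
import pytest

from mkphylo.simulate import CharacterMatrix, SimulationConfig, generate_model_tree, simulate_characters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tree20():
    """A 20-taxon short-branch model tree (fixed seed)."""
    return generate_model_tree(20, seed=5)


@pytest.fixture
def matrix20(tree20):
    """A 350-character single-rate matrix simulated on tree20."""
    config = SimulationConfig(n_characters=350, rate_mode="single",
                              gamma_shape=None, mean_rate=1.0, seed=7)
    return simulate_characters(tree20, config)


def random_matrix(taxa, n_chars, seed, missing_fraction=0.0):
    """A uniform random binary matrix (no tree signal)."""
    rng = np.random.default_rng(seed)
    data = rng.integers(0, 2, size=(len(taxa), n_chars)).astype(np.int8)
    if missing_fraction:
        mask = rng.random(data.shape) < missing_fraction
        data[mask] = -1
    return CharacterMatrix(list(taxa), data, np.ones(n_chars))
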