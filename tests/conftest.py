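import numpy as np
import pytest

from stabfs import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def toy4():
    """The 4-subject, 2-feature hand-computable fixture."""
    X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
    y = np.array([0, 0, 1, 1])
    return X, y


@pytest.fixture(scope="session")
def two_blobs():
    """40 points in two well-separated blobs differing only in feature 0."""
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 20)
    X = rng.normal(size=(40, 6))
    X[:, 0] += 3.0 * (2 * y - 1)
    return X, y


@pytest.fixture(scope="session")
def strong_signal():
    """Planted mean-shift cohort: every supervised filter should find it."""
    return generate_dataset(SyntheticConfig(
        n_subjects=400, n_features=30, n_informative=10, effect_size=3.0,
        n_redundant_blocks=0, block_size=0, seed=11,
    ))


@pytest.fixture(scope="session")
def null_signal():
    """No class signal at all: the pipeline should hover at chance AUC."""
    return generate_dataset(SyntheticConfig(
        n_subjects=200, n_features=50, n_informative=0, effect_size=0.0,
        n_redundant_blocks=0, block_size=0, seed=5,
    ))
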