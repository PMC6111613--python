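import numpy as np
import pytest

from orientinv import simulate


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete dataset: 3 subjects x 5 classes x 8 segments x 2 units."""
    return simulate.simulate_dataset(n_subjects=3, n_classes=5, minutes=2.0 / 3.0,
                                     units=2, seed=7)


@pytest.fixture(scope="session")
def gaussian_benchmark():
    """Separable 3-class Gaussian benchmark (pairwise mean distance 6*sqrt(2) sigma)."""
    rng = np.random.default_rng(0)
    means = 6.0 * np.eye(3)
    X = np.concatenate([rng.normal(m, 1.0, (60, 3)) for m in means])
    y = np.repeat(np.arange(3), 60)
    Xte = np.concatenate([rng.normal(m, 1.0, (40, 3)) for m in means])
    yte = np.repeat(np.arange(3), 40)
    return X, y, Xte, yte


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
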