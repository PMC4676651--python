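import numpy as np
import pytest

from airtree import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom1():
    """Single straight tube (trachea only), noise-free."""
    return generate_phantom(PhantomSpec(generations=1))


@pytest.fixture(scope="session")
def phantom3():
    """Three-generation binary tree, noise-free."""
    return generate_phantom(PhantomSpec(generations=3))


@pytest.fixture(scope="session")
def phantom4():
    """Four-generation binary tree (15 branches), noise-free."""
    return generate_phantom(PhantomSpec(generations=4))


@pytest.fixture(scope="session")
def noisy4():
    """Four-generation tree with 20 HU Gaussian noise."""
    return generate_phantom(PhantomSpec(generations=4, noise_sigma_hu=20.0, seed=11))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    return 2.0 * inter / (np.count_nonzero(a) + np.count_nonzero(b))
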