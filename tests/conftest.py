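import numpy as np
import pytest

from rarereg import GenotypeMatrix, GenotypeProfile, SCENARIOS, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def toy_genotypes():
    """Six individuals, three variants with distinct MAFs (no missing)."""
    values = np.array(
        [
            [0, 1, 0],
            [1, 0, 0],
            [0, 1, 1],
            [0, 0, 0],
            [2, 1, 0],
            [0, 1, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix.from_values(values, ["vA", "vB", "vC"])


@pytest.fixture
def small_dataset(rng):
    """A small simulated gene with signal, for end-to-end tests."""
    prof = GenotypeProfile(150, 15, 12, name="tiny")
    return simulate_dataset(prof, SCENARIOS["I.1"], rng)


@pytest.fixture
def regression_problem(rng):
    """Full-rank random regression problem with real signal."""
    X = rng.normal(size=(60, 8))
    beta = np.array([1.5, -1.0, 0, 0, 0.5, 0, 0, 0])
    y = X @ beta + rng.normal(size=60)
    return X, y
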