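import numpy as np
import pytest

from gpbench import GenotypeMatrix, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """10 lines x 20 markers, fully observed, no monomorphic columns."""
    return simulate_genotypes(10, 20, maf_range=(0.3, 0.5), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def ridge_fixture():
    """Standardized n=20, p=5 regression fixture for conjugate oracles."""
    rng = np.random.default_rng(3)
    n, p = 20, 5
    X = rng.standard_normal((n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    beta = rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n) * 0.5
    return X, y
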