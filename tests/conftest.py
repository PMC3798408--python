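import numpy as np
import pytest

from stratclust.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_genotypes(values) -> GenotypeMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GenotypeMatrix([f"s{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], values)


@pytest.fixture
def small_genotypes():
    return make_genotypes([
        [0, 1, 2, 0],
        [1, np.nan, 2, 0],
        [2, 1, np.nan, 1],
        [0, 0, 2, 1],
        [1, 1, 2, np.nan],
    ])


def random_genotypes(rng, n, m, missing_rate=0.2) -> GenotypeMatrix:
    vals = rng.integers(0, 3, size=(n, m)).astype(float)
    mask = rng.random((n, m)) < missing_rate
    # keep every row and column at least partly observed
    for i in range(n):
        if mask[i].all():
            mask[i, rng.integers(m)] = False
    for j in range(m):
        if mask[:, j].all():
            mask[rng.integers(n), j] = False
    vals[mask] = np.nan
    return make_genotypes(vals)
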