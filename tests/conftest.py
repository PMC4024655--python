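import numpy as np
import pytest

from mtgp import GenotypeMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genotypes():
    """3 samples x 2 markers, complete, two populations."""
    return GenotypeMatrix(
        ["s1", "s2", "s3"],
        ["m1", "m2"],
        np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
        np.array(["A", "A", "B"]),
    )


@pytest.fixture
def random_genotypes(rng):
    """40 samples x 25 markers with some missing cells, two populations."""
    codes = rng.integers(0, 3, size=(40, 25)).astype(float)
    miss = rng.random((40, 25)) < 0.05
    codes[miss] = np.nan
    labels = np.array(["A"] * 15 + ["B"] * 25)
    return GenotypeMatrix(
        [f"s{i}" for i in range(40)],
        [f"m{j}" for j in range(25)],
        codes,
        labels,
    )


@pytest.fixture
def small_training_problem(rng):
    """A small two-population regression with a few real signals."""
    n1, n2, m = 40, 60, 30
    X1 = rng.integers(0, 3, size=(n1, m)).astype(float)
    X2 = rng.integers(0, 3, size=(n2, m)).astype(float)
    beta = np.zeros(m)
    beta[[3, 11, 20]] = [1.0, -0.8, 0.6]
    y1 = X1 @ beta + rng.normal(0, 1.0, n1)
    y2 = X2 @ beta + rng.normal(0, 1.0, n2)
    return {"A": X1, "B": X2}, {"A": y1, "B": y2}


def make_phenotypes(sample_ids, labels, values):
    return PhenotypeTable(sample_ids, np.asarray(labels, dtype=object), values)
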