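import numpy as np
import pytest

from pathtask.types import (
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_labels():
    return PhenotypeLabels(["s1", "s2", "s3", "s4"], np.array([0, 0, 1, 1]))


@pytest.fixture
def small_expression(rng):
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(genes, samples, rng.normal(size=(10, 6)))


@pytest.fixture
def small_genotypes(rng):
    snps = [f"snp{i}" for i in range(8)]
    samples = [f"s{i}" for i in range(6)]
    return GenotypeMatrix(snps, samples, rng.integers(0, 3, size=(8, 6)))


@pytest.fixture
def small_sets():
    return GeneSetCollection(
        {"A": ["g0", "g1", "g2"], "B": ["g3", "g4"], "C": ["g0", "g5", "g9"]}
    )
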