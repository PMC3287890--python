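import numpy as np
import pytest

from burdenset import GeneMap, GenotypeMatrix, Phenotype


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_geno():
    """Six individuals, five variants in two genes; mixed rare/common."""
    dosages = np.array(
        [
            [0, 1, 0, 0, 2],
            [1, 0, 0, 0, 1],
            [0, 1, 0, 1, 0],
            [0, 2, 0, 0, 1],
            [0, 0, 0, 0, 2],
            [0, 1, 0, 0, 1],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        dosages,
        [f"s{i}" for i in range(6)],
        ["v1", "v2", "v3", "v4", "v5"],
    )


@pytest.fixture
def tiny_map():
    return GeneMap({"GA": [0, 1, 2], "GB": [3, 4]}, n_variants=5)


@pytest.fixture
def tiny_pheno(tiny_geno, rng):
    return Phenotype(list(tiny_geno.sample_ids), rng.standard_normal(6))


def random_genotypes(rng, n, m, maf_low=0.05, maf_high=0.4, missing_rate=0.0):
    """Helper: random HWE genotype matrix (importable from conftest)."""
    maf = rng.uniform(maf_low, maf_high, size=m)
    d = rng.binomial(2, maf, size=(n, m)).astype(float)
    if missing_rate:
        d[rng.random((n, m)) < missing_rate] = np.nan
    return GenotypeMatrix(d, [f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)])
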