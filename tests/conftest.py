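import numpy as np
import pytest

from rpabc.popdata import GenotypeTable, HaplotypeAlignment, PopulationPartition


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926)


def random_genotype_table(rng, n=12, n_loci=4, missing_rate=0.1,
                          n_pops=2) -> GenotypeTable:
    alleles = rng.integers(8, 20, size=(n, n_loci, 2))
    miss = rng.random((n, n_loci)) < missing_rate
    alleles[miss] = -1
    locality = [f"pop{1 + (i * n_pops) // n}" for i in range(n)]
    return GenotypeTable([f"ind{i:03d}" for i in range(n)],
                         [f"loc{j}" for j in range(n_loci)], alleles,
                         locality=locality)


@pytest.fixture
def toy_geno():
    """Six individuals, two loci, no missing data: hand-checkable."""
    alleles = np.array([
        [[10, 12], [5, 5]],
        [[10, 10], [5, 6]],
        [[12, 12], [6, 6]],
        [[10, 12], [5, 6]],
        [[12, 14], [5, 5]],
        [[10, 14], [6, 6]],
    ])
    return GenotypeTable([f"i{k}" for k in range(6)], ["A", "B"], alleles)


@pytest.fixture
def toy_alignment():
    """Four 10-bp sequences with hand-placed mutations.

    Site 2: C in s1 only (singleton); site 5: T in s2+s3 (shared);
    site 9: G in s3 only (singleton).
    """
    return HaplotypeAlignment(
        ["s0", "s1", "s2", "s3"],
        ["AAAAAAAAAA",
         "AACAAAAAAA",
         "AAAAATAAAA",
         "AAAAATAAAG"])


@pytest.fixture
def two_pop_partition():
    return PopulationPartition(
        {f"i{k}": ("p1" if k < 3 else "p2") for k in range(6)}, ["p1", "p2"])
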