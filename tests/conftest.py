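import numpy as np
import pytest

from escapetrace.dataset import GenotypeDataset, Locus


GENEPOP_2POP = """Example seabream panel
LocA
LocB
POP
a1 , 0102 0303
a2 , 0101 0304
a3 , 0202 0000
POP
b1 , 0103 0303
beach , 0102 0404
"""


@pytest.fixture
def genepop_file(tmp_path):
    path = tmp_path / "example.gen"
    path.write_text(GENEPOP_2POP)
    return path


def make_dataset(genotype_lists, n_alleles, pop_sizes):
    """Build a dataset from explicit allele-index genotypes.

    genotype_lists: list over individuals of list over loci of (a, b) index
    pairs (or None for missing).
    """
    n = len(genotype_lists)
    L = len(genotype_lists[0])
    g = np.full((n, L, 2), -1, dtype=np.int16)
    for i, row in enumerate(genotype_lists):
        for li, pair in enumerate(row):
            if pair is not None:
                g[i, li] = pair
    loci = [Locus(f"L{li+1}", tuple(range(1, k + 1)))
            for li, k in enumerate(n_alleles)]
    pop_index = np.repeat(np.arange(len(pop_sizes)), pop_sizes)
    names = [f"pop{p+1}" for p in range(len(pop_sizes))]
    return GenotypeDataset(loci, names, pop_index, g)


@pytest.fixture
def biallelic_two_pops():
    """Two populations of 10, fixed for alternate alleles at one locus."""
    rows = [[(0, 0)]] * 10 + [[(1, 1)]] * 10
    return make_dataset(rows, [2], [10, 10])
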