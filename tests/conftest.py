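import numpy as np
import pytest

from ttrees.genotype_data import GenotypeDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """60 individuals x 12 SNPs with a weakly informative SNP 3."""
    n, p = 60, 12
    G = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    logits = 1.2 * (G[:, 3] - 1)
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(np.uint8)
    if y.min() == y.max():  # keep both classes present
        y[0] = 1 - y[0]
    return GenotypeDataset(G, y, [f"rs{i}" for i in range(p)])


def make_genotypes(rng, n, p):
    return rng.integers(0, 3, size=(n, p)).astype(np.int8)
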