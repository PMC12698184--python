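import numpy as np
import pytest

from epiroadmap.intervals import GeneModel, GenomicInterval, PeakSet
from epiroadmap.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study conditions: 2000 genes, 4 stages, seed 42."""
    return generate_dataset(SyntheticConfig(), seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same design with jitter, count and expression noise all off."""
    return generate_dataset(SyntheticConfig.noiseless(), seed=42)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000,
                     max_width=2_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + width))
    return out


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel.from_body(f"g{i:03d}", str(rng.choice(chroms)),
                                         strand, start, start + 1_000))
    return genes
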