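import numpy as np
import pytest

from epirepeat import Genome, GenomicInterval, IntervalSet, generate_dataset


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic dataset at seed 1 (shared; treat as read-only)."""
    return generate_dataset(seed=1)


def random_interval_set(rng, genome, n, max_len=2000, min_len=10) -> IntervalSet:
    """Random intervals on a genome, for oracle comparisons."""
    ivs = []
    for _ in range(n):
        chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
        clen = genome.length(chrom)
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, clen - length + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs, genome=genome)
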