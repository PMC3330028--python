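import numpy as np
import pytest

from pphs.types import HaplotypePair, Read, ReadSets, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


def make_readsets(reads, m):
    return ReadSets.from_reads(reads, m)


@pytest.fixture
def small_params():
    """A tiny but realistic operating point: 5 individuals, 10 SNPs."""
    return SimulationParams(
        n_individuals=5,
        m_snps=10,
        coverage_k=5.0,
        read_length_l=400,
        error_rate=0.02,
        region_length=11000,
        seed=7,
    )


def reads_from_haplotype_pairs(pairs, n_copies=1, sites=None):
    """Noiseless full-coverage reads: each haplotype copied as reads."""
    out = []
    for pair in pairs:
        m = len(pair)
        s = list(range(m)) if sites is None else list(sites)
        for c in range(n_copies):
            for tag, h in (("a", pair.h1), ("b", pair.h2)):
                obs = tuple((j, h[j]) for j in s)
                out.append(Read(pair.individual_id, f"{pair.individual_id}_{tag}{c}", obs))
    return ReadSets.from_reads(out, len(pairs[0]))
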