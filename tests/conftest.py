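import numpy as np
import pytest

from bafdomains import GeneModel, GenomicInterval, Peak, SignalTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def random_intervals(rng, n_max=50, coord_max=100_000, chroms=("chr1", "chr2")):
    n = int(rng.integers(0, n_max + 1))
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, coord_max - 1))
        width = int(rng.integers(1, 2_000))
        out.append(GenomicInterval(chrom, start, min(start + width, coord_max)))
    return out


@pytest.fixture
def small_genes():
    return [
        GeneModel("geneA", "chr1", "+", 1_000, 5_000),
        GeneModel("geneB", "chr1", "-", 10_000, 14_000),
        GeneModel("geneC", "chr2", "+", 2_000, 6_000),
    ]


def constant_track(value, chrom="chr1", end=1_000_000, normalized=True):
    return SignalTrack(
        {chrom: [(0, end, value)]}, total_fragments=10_000_000,
        normalized=normalized,
    )
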