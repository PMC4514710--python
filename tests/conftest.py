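import numpy as np
import pytest

from dgftools.conservation import ConservationTrack
from dgftools.genes import GeneModel
from dgftools.intervals import GenomicInterval, IntervalSet
from dgftools.motifs import MotifModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sharp_motif():
    """4-column motif with IC exactly (2, 1, 1, 0): consensus ACCN."""
    probs = np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.5, 0.5, 0.0, 0.0],
        [0.5, 0.5, 0.0, 0.0],
        [0.25, 0.25, 0.25, 0.25],
    ])
    return MotifModel("TEST_IC", probs)


def random_motif(rng, length=6, concentration=0.5):
    """Random Dirichlet motif for property tests."""
    probs = rng.dirichlet([concentration] * 4, size=length)
    return MotifModel("RND", probs)


def make_intervals(coords, chrom="chr1", label=""):
    return IntervalSet((GenomicInterval(chrom, s, e) for s, e in coords), label=label)


@pytest.fixture
def simple_genes():
    """Two genes on chr1: one per strand, two exons each."""
    plus = GeneModel("geneA", "chr1", "+", 10_000, 20_000,
                     exons=((10_000, 12_000), (18_000, 20_000)),
                     utr3=((19_500, 20_000),))
    minus = GeneModel("geneB", "chr1", "-", 50_000, 60_000,
                      exons=((50_000, 52_000), (58_000, 60_000)),
                      utr3=((50_000, 50_500),))
    return [plus, minus]
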