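import numpy as np
import pytest

from cotarget.io_core import GenomeBuild, GeneModel, Peak, PeakSetPair


@pytest.fixture
def toy_genome() -> GenomeBuild:
    return GenomeBuild({"chrI": 1_000_000, "chrII": 800_000})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pair(rng, n_a=50, n_b=60, chroms=("chrI", "chrII"),
                length=100_000, wmin=50, wmax=500) -> PeakSetPair:
    """Random peak sets on a small genome, for oracle-equivalence tests."""
    genome = GenomeBuild({c: length for c in chroms})

    def make(n, label):
        peaks = []
        for i in range(n):
            chrom = chroms[rng.integers(len(chroms))]
            w = int(rng.integers(wmin, wmax + 1))
            start = int(rng.integers(0, length - w))
            peaks.append(Peak(chrom, start, start + w, name=f"{label}{i}"))
        return tuple(peaks)

    return PeakSetPair(make(n_a, "a"), make(n_b, "b"), genome)


def gene_row(gid, chrom="chrI", strand="+", tss=5000) -> GeneModel:
    return GeneModel(gid, chrom, strand, tss)
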