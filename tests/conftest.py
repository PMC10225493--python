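import numpy as np
import pytest

from xykit.kmers import KmerParams
from xykit.sim import SimGenomeParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome_params():
    """200 kb sex chromosome + 100 kb autosome; 40 kb SDR with 6 kb insertion."""
    return SimGenomeParams(
        chrom_lengths=(200_000, 100_000),
        sex_chrom_index=0,
        sdr_interval=(100_000, 140_000),
        msr_length=6_000,
        sdr_divergence=0.02,
        seed=7,
    )


@pytest.fixture
def k4_params():
    return KmerParams(k=4, prefix="AG", min_total_count=10)
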