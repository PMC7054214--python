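import numpy as np
import pytest

from svdriverscan.genome import GenomeDef, make_bins
from svdriverscan.simulate import SimulationConfig


@pytest.fixture
def small_genome():
    return GenomeDef(("chr1", "chr2"), (1_000_000, 600_000))


@pytest.fixture
def small_bins(small_genome):
    return make_bins(small_genome, 100_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sim_config():
    """A lean cohort: 2 chromosomes, 100 bins, 50 samples."""
    return SimulationConfig(seed=7, n_chroms=2, chrom_length=5_000_000,
                            n_samples=50, rearr_per_sample=10.0)


def bh_reference(p):
    """Literal step-up reference implementation of Benjamini-Hochberg.

    Walks ranks from largest p to smallest, tracking the running minimum
    of m * p_(j) / j; independent of the vectorized production code.
    """
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q
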