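import numpy as np
import pytest

from lrtaps.simulate import SimParams, simulate_genome, simulate_reads
from lrtaps.strand import normalize_strand


def normalized(sim):
    """Truth alignments with flags normalized to biological strand."""
    return [normalize_strand(r) for r in sim.aligned_reads()]


@pytest.fixture(scope="session")
def noiseless_sim():
    """200-kb genome, 2000 reads, perfect chemistry and error-free sequencing."""
    genome, meth = simulate_genome(genome_size=200_000, seed=41)
    params = SimParams(
        n_reads=2000,
        conversion_rate=1.0,
        false_conversion_cpg=0.0,
        false_conversion_cph=0.0,
        error_rate=0.0,
        seed=41,
    )
    sim = simulate_reads(genome, meth, params)
    return genome, meth, params, sim


@pytest.fixture(scope="session")
def spikein_sim():
    """All reads drawn from the 4-kb spike-in, published chemistry rates,
    no sequencing error — the parameter-recovery condition."""
    genome, meth = simulate_genome(genome_size=20_000, seed=13)
    params = SimParams(
        n_reads=600,
        spikein_fraction=1.0,
        error_rate=0.0,
        fragment_min=3000,
        seed=13,
    )
    sim = simulate_reads(genome, meth, params)
    return genome, meth, params, sim
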