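import numpy as np
import pytest

import chromsig as cs
from chromsig.scan import pearson


@pytest.fixture(scope="session")
def sim400():
    """400 synthetic profiles (100 per cluster) with moderate noise."""
    spec = cs.SyntheticSpec((100, 100, 100, 100), noise_sd=0.4, seed=1)
    return cs.simulate_profiles(spec)


@pytest.fixture(scope="session")
def trained400(sim400):
    matrix, _ = sim400
    return cs.train(matrix, K=4, seed=1)


@pytest.fixture(scope="session")
def genome2mb():
    """2 Mb toy chromosome with 20 embedded low-noise signatures."""
    spec = cs.SyntheticSpec(noise_sd=0.1, seed=2)
    return cs.simulate_genome(spec, n_sites=20, genome_length=2_000_000)


@pytest.fixture(scope="session")
def generator_to_trained(trained400):
    """Map generator cluster ids (1=pre-TSS, 2=post-TSS, 3=peak) to the
    canonical cluster numbering of the trained model, by best pattern
    correlation."""
    gen = cs.make_patterns()
    return {
        k: max(trained400.patterns, key=lambda p: pearson(p.mean_log, gen[k - 1])).cluster_id
        for k in (1, 2, 3)
    }


def constant_track(values=(1.0, 2.0, 3.0, 4.0), n_bins=200, chrom="chr1"):
    return cs.GenomeTrack(
        chrom, [np.full(n_bins, v) for v in values], bin_size=100, offset=1
    )


@pytest.fixture
def flat_track():
    return constant_track()
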