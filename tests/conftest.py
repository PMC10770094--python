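import numpy as np
import pandas as pd
import pytest

from methepi.config import SyntheticConfig
from methepi.context import site_frame
from methepi.synthetic import generate_reference, simulate_methylome_set


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_records(rng, n, n_chroms=2, max_pos=10_000):
    """Random site-record frame with unique (chrom, start, strand) keys."""
    chroms = rng.integers(1, n_chroms + 1, size=n)
    pos = rng.choice(max_pos, size=n, replace=False)
    strand = rng.choice(["+", "-"], size=n)
    coverage = rng.poisson(8, size=n)
    n_meth = rng.binomial(coverage, rng.uniform(0, 1, size=n))
    n_ill = rng.binomial(coverage, 0.1, size=n)
    return site_frame(
        chrom=[f"chr{c}" for c in chroms],
        start=np.sort(pos).astype(np.int64),
        strand=strand,
        context=rng.choice(["CG", "CHG", "CHH"], size=n),
        n_meth=n_meth,
        n_unmeth=coverage - n_meth,
        n_illegitimate=n_ill,
    )


@pytest.fixture(scope="session")
def small_methylome():
    """Shared small four-genotype simulation (8 kb genome, triplicates)."""
    config = SyntheticConfig(seed=11, genome_length=8000)
    reference = generate_reference(config)
    methylomes, truth = simulate_methylome_set(config, reference)
    return config, reference, methylomes, truth
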