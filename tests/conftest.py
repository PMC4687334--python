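import numpy as np
import pytest

from binqtl import BreedingScheme, GenomeSpec, simulate_population


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec.uniform(
        [("chr1", 10_000_000, 50.0), ("chr2", 8_000_000, 40.0)], snps_per_chrom=41
    )


@pytest.fixture(scope="session")
def dh_population(small_genome):
    """120 DH lines from a plain F2 (one effective meiosis layer)."""
    return simulate_population(
        small_genome, BreedingScheme(j=2, i=1, n_lines=120), seed=42
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
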