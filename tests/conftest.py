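import numpy as np
import pytest

from npbss import CountSpec, simulate
from npbss.synthetic import random_genome


@pytest.fixture(scope="session")
def genome_1mb():
    """1 Mb i.i.d. random genome, the standard simulation substrate."""
    return random_genome(1_000_000, seed=42)


@pytest.fixture(scope="session")
def genome_small():
    return random_genome(100_000, seed=3)


@pytest.fixture(scope="session")
def default_run(genome_1mb):
    """300 reads at all-default parameters, shared across unit tests."""
    return list(
        simulate(
            genome_1mb,
            CountSpec(mode="explicit_n", n=300, mean_len=8500),
            seed=1,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
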