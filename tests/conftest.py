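import numpy as np
import pytest

from evonet.regulatory_genome import Genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240828)


def random_genome(rng, n=5, L=12):
    return Genome(
        rng.integers(0, 2, size=(n, L), dtype=np.uint8),
        rng.integers(0, 2, size=(n, L), dtype=np.uint8),
    )


@pytest.fixture
def genome_factory():
    return random_genome
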