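import numpy as np
import pytest

from spikemap import simcross
from spikemap.simcross import Chromosome, GenomeModel


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two small chromosomes, 1 cM/Mb: cheap but recombinationally active."""
    return GenomeModel(
        [Chromosome("chr1", 100_000_000, 1.0), Chromosome("chr2", 80_000_000, 1.0)]
    )


@pytest.fixture
def group1_genome() -> GenomeModel:
    return simcross.default_wheat_genome()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
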