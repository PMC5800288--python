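import numpy as np
import pytest

from pmhd.element import make_element_model
from pmhd.genome import PlantSpec, make_genome, plant_insertions


@pytest.fixture(scope="session")
def element():
    return make_element_model(1)


@pytest.fixture(scope="session")
def genome():
    """Small two-chromosome genome with a dozen annotated clusters."""
    return make_genome(n_chromosomes=2, chrom_length=400_000, n_clusters=12, seed=7)


@pytest.fixture(scope="session")
def planted(genome):
    spec = [PlantSpec("uniform", "FP", 1.0) for _ in range(8)] + [
        PlantSpec("in-cluster", "KP", 0.5) for _ in range(4)
    ]
    return plant_insertions(genome, spec, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
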