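import numpy as np
import pytest
from hypothesis import settings

from tc1kit import build_master_element, plant_copies
from tc1kit.synth import _random_dna

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def master():
    """Default-geometry master element (1563 bp, 27-bp TIR, DD37E)."""
    return build_master_element(seed=3)


@pytest.fixture(scope="session")
def planted_dataset(master):
    """200-kb genome with 12 planted copies (3 truncated, 3 inactivated)."""
    rng = np.random.default_rng(101)
    host = _random_dna(rng, 200_000)
    genome, truth = plant_copies(
        host, master, 12, divergence=0.02, truncate_frac=0.25,
        inactivate_frac=0.25, seed=7)
    return genome, truth


@pytest.fixture(scope="session")
def random_genome():
    return _random_dna(np.random.default_rng(55), 100_000)
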