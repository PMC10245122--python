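import numpy as np
import pytest

from hicevo.matrix import BinGrid, ContactMatrix
from hicevo.synthetic import SimulationSpec, simulate_species_set


@pytest.fixture
def small_grid():
    return BinGrid("chr1", 10_000, 20)


@pytest.fixture
def random_symmetric(small_grid):
    rng = np.random.default_rng(42)
    a = rng.integers(1, 20, size=(20, 20)).astype(float)
    a = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix(small_grid, a)


@pytest.fixture(scope="session")
def default_species_set():
    """The default 40-Mb, three-species study conditions (seed 1)."""
    return simulate_species_set(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def pei_species_set():
    """Deep 1.5-Mb fixture used for interaction calling and classification."""
    spec = SimulationSpec(
        chrom_length=1_500_000,
        depth=100_000,
        n_loops=12,
        loop_distance_range=(100_000, 300_000),
        compartment_block_range=(400_000, 1_000_000),
        tad_length_range=(300_000, 600_000),
        loop_amplitude=5.0,
        seed=1,
    )
    return simulate_species_set(spec)
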