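import numpy as np
import pytest

from tagimpute import (
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    SimulationConfig,
    simulate_population,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    return MarkerMap.from_positions([100, 500, 1200, 2500, 4000])


def random_panel(rng, n_hap=10, n_markers=20, spacing=1000):
    """A random phased panel with every marker segregating."""
    while True:
        alleles = rng.integers(0, 2, size=(n_hap, n_markers)).astype(np.int8)
        freq = alleles.mean(axis=0)
        if np.all((freq > 0) & (freq < 1)):
            break
    markers = MarkerMap.from_positions(np.arange(1, n_markers + 1) * spacing)
    return HaplotypePanel(alleles, markers)


def random_genotypes(rng, n_ind=8, n_markers=12, missing_rate=0.1, spacing=1000):
    dosage = rng.integers(0, 3, size=(n_ind, n_markers)).astype(np.int8)
    miss = rng.random(dosage.shape) < missing_rate
    dosage[miss] = -1
    markers = MarkerMap.from_positions(np.arange(1, n_markers + 1) * spacing)
    return GenotypeMatrix(dosage, markers)


@pytest.fixture(scope="session")
def sim_panel():
    """One medium simulated population shared by read-only tests."""
    cfg = SimulationConfig(
        n_markers=300, chromosome_length_bp=15_000_000, seed=2024
    )
    return simulate_population(cfg)
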