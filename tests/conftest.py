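import numpy as np
import pytest

from barcodekit import SimulationConfig, simulate_library


@pytest.fixture(scope="session")
def clean_sim():
    """Small clean library: 20 species x 4 specimens, no planted anomalies."""
    cfg = SimulationConfig(seed=11, n_families=5, genera_per_family=2,
                           species_per_genus=2, specimens_per_species=4,
                           query_fraction=0.25)
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def anomalous_sim():
    """Library with cryptic splits, singletons and query misidentifications."""
    cfg = SimulationConfig(seed=23, cryptic_fraction=0.1, cryptic_depth=0.06,
                           singleton_fraction=0.15, misid_rate=0.02,
                           query_fraction=0.3, region_sorting=True)
    return simulate_library(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
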