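import numpy as np
import pytest

from genomechaos import synthetic
from genomechaos.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact study-regime configuration used across the suite."""
    return SimulationConfig(seed=11, n_chromosomes=2, chrom_length_bp=200_000,
                            sv_counts={"DEL": 30, "DUP": 12, "INV": 12, "TRA": 16})


@pytest.fixture(scope="session")
def sim_bundle(small_config):
    """(reference, genes, calls, truths) from one deterministic simulation."""
    return synthetic.simulate_sv_truth_set(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
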