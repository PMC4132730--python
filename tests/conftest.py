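import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tetrakit import SimulationConfig, simulate_tetrad_population, tally

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    """Interference-free (Poisson) placement, two adjacent 5 cM intervals."""
    return SimulationConfig(
        marker_positions=(0.15, 0.20, 0.25),
        chrom_length=0.4,
        nu=1.0,
        lambda1=0.8,
        lambda2=0.0,
        n_meioses=50_000,
        seed=101,
    )


@pytest.fixture(scope="session")
def null_population(null_config):
    return simulate_tetrad_population(null_config)


@pytest.fixture(scope="session")
def null_counts(null_population):
    return tally(null_population)


@pytest.fixture(scope="session")
def interference_config(null_config) -> SimulationConfig:
    """Strongly interfering class I placement (gamma shape 10)."""
    return SimulationConfig(
        marker_positions=null_config.marker_positions,
        chrom_length=null_config.chrom_length,
        nu=10.0,
        lambda1=0.8,
        lambda2=0.0,
        n_meioses=50_000,
        seed=202,
    )


@pytest.fixture(scope="session")
def interference_counts(interference_config):
    return tally(simulate_tetrad_population(interference_config))
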