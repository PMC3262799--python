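import pytest

from mircornet.io import CellTypeScheme
from mircornet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One fully generated synthetic cohort shared by read-only tests."""
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def scheme(default_config) -> CellTypeScheme:
    return default_config.scheme()


@pytest.fixture()
def toy_scheme() -> CellTypeScheme:
    """A minimal three-group scheme for hand-constructed matrices."""
    cts = ("cA", "cB", "cC")
    return CellTypeScheme(
        cell_types=cts,
        merge_map={c: c for c in cts},
        lineage_map={c: "myeloid" for c in cts},
    )
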