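import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cortexdiff as cd
from cortexdiff import pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> cd.SimulationConfig:
    """A reduced cohort for fast unit tests (not the full study conditions)."""
    return cd.SimulationConfig(n_hc=12, n_ms=36, seed=7)


@pytest.fixture(scope="session")
def tiny_config() -> cd.SimulationConfig:
    """14 regions on a 9x9x6 grid: small enough for voxel-loop oracles."""
    return cd.SimulationConfig(
        n_hc=4, n_ms=6, grid_shape=(9, 9, 6), n_regions=14, seed=3
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config) -> cd.ParcellationAtlas:
    return cd.make_toy_atlas(tiny_config)


@pytest.fixture(scope="session")
def default_study() -> cd.SyntheticStudy:
    """One full-size study at the default conditions (48 HC, 176 MS)."""
    return cd.simulate_study(cd.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_tables(default_study) -> pipeline.StudyTables:
    return pipeline.extract_study_tables(default_study)


@pytest.fixture(scope="session")
def plan() -> pipeline.AnalysisPlan:
    return pipeline.AnalysisPlan()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
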