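import numpy as np
import pytest

from rnflpca.config import CohortConfig
from rnflpca.registration import register_scans
from rnflpca.simulate import generate_cohort, generate_template_map


@pytest.fixture(scope="session")
def default_cfg() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def template(default_cfg):
    return generate_template_map(default_cfg)


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    """Desk-scale cohort used across tests: small but structurally complete."""
    return CohortConfig(n_glaucoma_participants=10, n_healthy_participants=6,
                        grid_h=60, grid_w=80, n_visits=5, n_boot=300, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def registered_small(small_cohort):
    cohort, _ = small_cohort
    order = cohort.table["scan_id"].tolist()
    maps = [cohort.maps[s] for s in order]
    stack, records = register_scans(maps)
    return stack, records


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
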