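import numpy as np
import pytest

from aphasiamap import spmodel
from aphasiamap.synthcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def network():
    return spmodel.build_network()


@pytest.fixture(scope="session")
def small_cache(network):
    """Cheap 15x15 grid cache for unit tests (coarse but well-formed)."""
    grid = spmodel.default_grid(15)
    return spmodel.GridCache.build(s_grid=grid, p_grid=grid, n_sims=1500, seed=42,
                                   network=network)


@pytest.fixture(scope="session")
def full_cache(network):
    """Study-condition cache: default 50x50 grid at 10^4 simulations.

    Built once per session; shared by the fitting and acceptance tests.
    """
    return spmodel.GridCache.build(n_sims=10_000, seed=3, network=network)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (53 patients, no volumes)."""
    return generate_cohort(CohortConfig(seed=7), with_volumes=False)


@pytest.fixture(scope="session")
def volume_cohort():
    """A full default cohort including volumes (used by lesion-mapping tests)."""
    return generate_cohort(CohortConfig(seed=7), with_volumes=True)
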