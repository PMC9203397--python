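import warnings

import pytest

from mpnorm.grid import build_maia_grid
from mpnorm.normative import build_reference
from mpnorm.simulate import CohortConfig, generate_healthy_cohort


@pytest.fixture(scope="session")
def grid():
    return build_maia_grid()


@pytest.fixture(scope="session")
def healthy80(grid):
    """An 80-eye synthetic healthy cohort at the default generator settings."""
    return generate_healthy_cohort(CohortConfig(n_eyes=80, seed=7), grid)


@pytest.fixture(scope="session")
def reference80(grid, healthy80):
    return build_reference(healthy80, grid)
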