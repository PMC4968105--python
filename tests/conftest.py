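import numpy as np
import pytest

from bispec import load_parameter_fixture
from bispec.mc import MCBoxConfig


@pytest.fixture(scope="session")
def panel():
    """(variants, cells, assay) from the packaged parameter fixture."""
    return load_parameter_fixture()


@pytest.fixture(scope="session")
def variants(panel):
    return panel[0]


@pytest.fixture(scope="session")
def cells(panel):
    return panel[1]


@pytest.fixture(scope="session")
def assay(panel):
    return panel[2]


@pytest.fixture(scope="session")
def mc_cfg():
    """Fast-but-valid particle-simulation settings used throughout tests:
    50 us steps (inside the 0.1-100 us design range, and satisfying the
    surface-pair step guard) with coarse frame recording."""
    return MCBoxConfig(dt_s=5e-5, rng_seed=42, n_replicates=3,
                       record_every_s=10.0)
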