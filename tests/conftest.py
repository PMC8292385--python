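import numpy as np
import pytest
from hypothesis import settings

import pblev

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """Small synthetic common-variant panel shared across tests."""
    return pblev.synthetic_panel(500, seed=11)


@pytest.fixture(scope="session")
def panel2000():
    return pblev.synthetic_panel(2000, seed=1)


@pytest.fixture(scope="session")
def arch():
    return pblev.ArchitectureSpec("polygenic")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def low_trait():
    """The 'low' reference setting: h2_PB=0.3, h2_LEV=0.03, f=0.005, K=0.01."""
    return pblev.TraitModel(
        h2_pb=0.3,
        lev=pblev.LevSpec.from_h2(0.03, 0.005),
        prevalence=0.01,
    )
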