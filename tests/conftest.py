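import numpy as np
import pytest

from toxgan.data import StudyScalers, ScalerState
from toxgan.fixtures import FixtureConfig, make_fixture
from toxgan.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by read-only tests: 5 compounds,
    4-dim descriptors, 60 conditions."""
    ds, gt, S = make_fixture(FixtureConfig(n_compounds=5, descriptor_dim=4, seed=42))
    return ds, gt, S


@pytest.fixture()
def identity_scalers(panel):
    """Scalers whose forward/inverse are the identity on [-1, 1]^n: handy
    for stub-model tests where profiles live in network space already."""
    n_cond = 6  # 4 descriptors + dose + time
    return StudyScalers(
        condition=ScalerState(np.full(n_cond, -1.0), np.full(n_cond, 1.0)),
        profile=ScalerState(np.full(len(panel), -1.0), np.full(len(panel), 1.0)),
    )
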