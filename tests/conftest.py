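import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from neqfe.pipeline import (  # noqa: E402
    BindingToy,
    double_well_softening,
    double_well_system,
    harmonic_pair,
)


@pytest.fixture(scope="session")
def harmonic_1_4():
    """The 1D harmonic k=1 / k=4 pair; exact dG = ln 2 kT."""
    return harmonic_pair()


@pytest.fixture(scope="session")
def double_well_6():
    """Asymmetric double well (6 kT barrier) and its softening (to 1.2 kT)."""
    return double_well_system(6.0), double_well_softening()


@pytest.fixture(scope="session")
def binding_toy():
    return BindingToy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
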