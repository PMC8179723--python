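import numpy as np
import pytest

from nifs import (
    AnnularProfile,
    GaussianEllipsoidProfile,
    Nifs3DProfile,
)

# nominal illumination geometry used throughout the tests
R0_FCS = 0.708e-6
KAPPA = 3.0
R0_NIFS = 60e-9
Z0_NIFS = 12e-9
A0 = 20e-9
B0 = 8e-9


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gauss_profile():
    return GaussianEllipsoidProfile(r0=R0_FCS, z0=KAPPA * R0_FCS)


@pytest.fixture
def nifs_profile():
    return Nifs3DProfile(r0=R0_NIFS, z0=Z0_NIFS)


@pytest.fixture
def annular_profile():
    return AnnularProfile(a0=A0, b0=B0)
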