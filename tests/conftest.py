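import numpy as np
import pytest

import fibretex as fx


@pytest.fixture(scope="session")
def geometry():
    """Microfocus WAXD geometry with full detector calibration."""
    return fx.default_geometry()


@pytest.fixture(scope="session")
def chi_fine():
    return np.arange(0.0, 360.0, 0.1)


@pytest.fixture(scope="session")
def chi_coarse():
    return (np.arange(360) + 0.5) * 1.0


@pytest.fixture(scope="session")
def untilted():
    """Single in-plane family, no tilts, moderate spread."""
    return fx.LamellaModel(0.0, 0.0, fx.FibreDistribution(0.0, 30.0))


def single_family_model(alpha=0.0, beta=0.0, gamma0=0.0, dgamma0=30.0, scale=1.0):
    return fx.TwoFamilyModel(
        ip=fx.LamellaModel(alpha, beta, fx.FibreDistribution(gamma0, dgamma0), scale=scale),
        op=fx.LamellaModel(0.0, 90.0, fx.FibreDistribution(0.0, 45.0), scale=0.0),
    )


@pytest.fixture(scope="session")
def make_single_family():
    return single_family_model
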