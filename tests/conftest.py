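import numpy as np
import pytest

from mechanofak import LandscapeParams, ProtocolSpec, PullingProtocol


@pytest.fixture(scope="session")
def fig4a_params() -> LandscapeParams:
    """Headline constrained-fit landscape: 28.5 kT, 0.86 nm, 6.6e6 nm^2/s."""
    return LandscapeParams(deltaG=28.5, x_b=0.86, D=6.6e6)


@pytest.fixture(scope="session")
def s7_params() -> LandscapeParams:
    """Unconstrained best fit: thermally unstable at zero force."""
    return LandscapeParams(deltaG=14.2, x_b=0.3, D=1.2e7)


@pytest.fixture(scope="session")
def paper_velocities() -> np.ndarray:
    return np.geomspace(6e-3, 1.0, 13)


@pytest.fixture
def protocol_mid() -> PullingProtocol:
    return PullingProtocol.from_kjmol(250.0, 0.1)


@pytest.fixture
def spec83() -> ProtocolSpec:
    return ProtocolSpec(seed=11)
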