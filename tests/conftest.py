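import pytest

from marsalt import (
    MARS_ENVIRONMENT,
    MARS_WIND,
    ParticleClass,
    hop_length,
    interpolant_curve,
)


@pytest.fixture(scope="session")
def mars_hop_1mm() -> float:
    """Unrounded Mars hop length for a 1 mm grain."""
    return hop_length(MARS_ENVIRONMENT, MARS_WIND, ParticleClass(1e-3))


@pytest.fixture(scope="session")
def mars_hop_0p125mm() -> float:
    """Unrounded Mars hop length for a 0.125 mm grain."""
    return hop_length(MARS_ENVIRONMENT, MARS_WIND, ParticleClass(1.25e-4))


@pytest.fixture(scope="session")
def anchor_curve():
    """Log-log interpolant through the three digitized anchors."""
    return interpolant_curve()
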