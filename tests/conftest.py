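import numpy as np
import pytest

from melanocycle import (GenotypeConfig, LightProtocol, LightSegment,
                         PhotocycleParams, TransductionParams)


@pytest.fixture(scope="session")
def params() -> PhotocycleParams:
    return PhotocycleParams()


@pytest.fixture(scope="session")
def tp() -> TransductionParams:
    return TransductionParams()


@pytest.fixture(scope="session")
def wt() -> GenotypeConfig:
    return GenotypeConfig()


@pytest.fixture
def short_pulse() -> LightProtocol:
    """10-s pulse with dark lead-in and tail, small enough for fast tests."""
    return LightProtocol([LightSegment(20.0, 10.0, 5e12)], total_duration_s=90.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
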