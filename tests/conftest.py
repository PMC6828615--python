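import numpy as np
import pytest

from hosebiofilm import (
    ImagingConfig,
    SimulationConfig,
    control_hose_config,
    generate_thickness_field,
)


@pytest.fixture
def control_cfg() -> SimulationConfig:
    return control_hose_config()


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A short hose (10 sections per half) for fast community/TCC tests."""
    return SimulationConfig(hose_length_cm=12.0, seed=7)


@pytest.fixture
def clean_img_cfg() -> ImagingConfig:
    return ImagingConfig(noise_sd=0.0)


@pytest.fixture
def control_field(control_cfg):
    return generate_thickness_field(control_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
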