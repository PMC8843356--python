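import numpy as np
import pytest

from cortios import AcquisitionConfig, ArtifactModel, HemodynamicTemplate
from cortios import synthetic as sd


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down acquisition: 64 x 64 px at 30 fps."""
    return AcquisitionConfig(height_px=64, width_px=64, frame_rate_fps=30.0,
                             pixel_pitch_um=7.5, seed=3)


@pytest.fixture(scope="session")
def scene(small_config):
    return sd.make_vessel_scene(small_config, n_vessels=2, seed=3)


@pytest.fixture(scope="session")
def green():
    return HemodynamicTemplate.green()


@pytest.fixture(scope="session")
def red():
    return HemodynamicTemplate.red()


@pytest.fixture(scope="session")
def quiet_artifacts():
    """Artifact-free, noise-free model for closed-form checks."""
    return ArtifactModel.none()
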