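import numpy as np
import pytest

from fringescan import simulate as sim
from fringescan.patterns import PatternSpec
from fringescan.pipeline import PipelineConfig, run_single_frame


@pytest.fixture(scope="session")
def spec256():
    return PatternSpec(width_px=256, height_px=256, period_px=16.0,
                       marker_index=8)


@pytest.fixture(scope="session")
def cap_frame(spec256):
    """Noise-free sphere-cap scene (256 px) processed end to end."""
    z = sim.sphere_cap_height((256, 256), radius_mm=300.0, cap_height_mm=40.0)
    scene = sim.SyntheticScene(height_mm=z)
    img, truth = sim.render(scene, spec256)
    frame = run_single_frame(img, PipelineConfig(pattern=spec256))
    return img, truth, frame


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
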