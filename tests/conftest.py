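import numpy as np
import pytest

from wormloco import CorralROI, RenderConfig, SimDesign, WormKinematics


@pytest.fixture
def small_kin() -> WormKinematics:
    return WormKinematics(body_length=30.0, body_width=4.0, n_segments=19)


@pytest.fixture
def small_cfg() -> RenderConfig:
    """A reduced scene (quarter-size corral, 40 frames) for fast tests."""
    return RenderConfig(frame_count=40, image_size=(128, 128),
                        corral_center=(64.0, 64.0), corral_radius=56.0, seed=7)


@pytest.fixture
def small_roi(small_cfg) -> CorralROI:
    return CorralROI.circle(small_cfg.image_size, small_cfg.corral_center,
                            small_cfg.corral_radius)


@pytest.fixture
def chronic_design() -> SimDesign:
    return SimDesign(seed=11)


def random_stack(rng: np.random.Generator, t: int = 6, h: int = 12,
                 w: int = 10, vmax: int = 255) -> np.ndarray:
    return rng.integers(0, vmax + 1, size=(t, h, w)).astype(np.uint8)
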