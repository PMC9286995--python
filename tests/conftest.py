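import numpy as np
import pytest

from lvseg.phantom import PhantomConfig


def make_disc(size: int, center, radius: float) -> np.ndarray:
    """Half-open disc rasterization used as an independent mask oracle."""
    rows, cols = np.mgrid[0:size, 0:size]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 < radius**2


@pytest.fixture
def tiny_phantom_cfg():
    """Small frames so per-test generation stays fast."""
    return PhantomConfig(
        image_size=64,
        endo_radius_px=(8.0, 11.0),
        wall_thickness_px=(3.0, 4.5),
        center_jitter_px=3.0,
        n_slices=3,
        seed=0,
    )


@pytest.fixture
def roi_phantom_cfg():
    """Phantom sized so a 64 px ROI plays the role of the 128 px ROI."""
    return PhantomConfig(
        image_size=96,
        endo_radius_px=(10.0, 16.0),
        wall_thickness_px=(4.0, 7.0),
        center_jitter_px=6.0,
        wobble_amp_px=1.0,
    )
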