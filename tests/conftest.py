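import numpy as np
import pytest

from choroidseg.synthetic import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    """64x64 noiseless-ish config used across module tests."""
    return SimConfig(
        width=64, height=64, n_bscans=6,
        axial_spacing=10.0, lateral_spacing=47.0, slice_spacing=100.0,
        mean_choroid_thickness=200.0, boundary_smoothness=24.0,
        csi_contrast=0.8, speckle_shape=np.inf, bit_depth=8, seed=3,
        bm_mean_row_frac=0.3, boundary_amplitude=4.0, thickness_variation=40.0,
    )


def random_trace(rng, width=32, height=64):
    """A random valid trace (BM above CSI everywhere)."""
    from choroidseg.trace import BoundaryTrace

    bm = rng.uniform(5, 25, size=width)
    csi = bm + rng.uniform(1, 30, size=width)
    return BoundaryTrace(bm, np.minimum(csi, height - 1))
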