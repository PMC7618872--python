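import numpy as np
import pytest

from topowarp import Grid2D, make_annulus, make_cardiac_prior


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def annulus_64():
    """Annulus prior on a 64x64 grid (outer radius 18, wall 5)."""
    return make_annulus(64, 64, outer_radius=18, wall=5)


@pytest.fixture(scope="session")
def cardiac_64():
    """3-channel cardiac scene prior (myo, rv, lv) on a 64x64 grid."""
    return make_cardiac_prior(64, 64, rv_position=7, myo_outer=14, myo_wall=4, rv_radius=7)


@pytest.fixture
def grid8():
    return Grid2D(8, 8)


def smooth_random_displacement(rng, H, W, amplitude=0.3, cycles=1.5):
    """Low-frequency random displacement for interpolation-level checks."""
    r, c = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    ph = rng.uniform(0, 2 * np.pi, size=4)
    u = np.stack(
        [
            np.sin(2 * np.pi * cycles * r / H + ph[0]) * np.cos(2 * np.pi * cycles * c / W + ph[1]),
            np.cos(2 * np.pi * cycles * r / H + ph[2]) * np.sin(2 * np.pi * cycles * c / W + ph[3]),
        ]
    )
    return amplitude * u
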