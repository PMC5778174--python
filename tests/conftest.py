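import numpy as np
import pytest
from scipy import ndimage as ndi

import cellwarp as cw


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def smooth_texture():
    """Band-limited random texture: every pixel carries gradient information."""
    r = np.random.default_rng(5)
    base = ndi.gaussian_filter(r.random((96, 96)), 2.0)
    base = (base - base.min()) / (base.max() - base.min())
    return cw.Image2D(base)


@pytest.fixture(scope="session")
def grid_phantom_64():
    return cw.make_phantom(cw.PhantomSpec(
        shape=(64, 64), pattern="grid", line_spacing=12, linewidth=3,
        blur_sigma=2.5, margin=8, seed=0))


@pytest.fixture(scope="session")
def bending_pair_64(grid_phantom_64):
    field = cw.make_field(cw.FieldSpec(kind="bending", amplitude=2.0),
                          grid_phantom_64.shape)
    return cw.make_pair(grid_phantom_64, field, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def ffd_pair_64(grid_phantom_64):
    field = cw.make_field(
        cw.FieldSpec(kind="custom_ffd", amplitude=2.0, spline_spacing=16.0,
                     seed=2), grid_phantom_64.shape)
    return cw.make_pair(grid_phantom_64, field, noise_sigma=0.0, seed=0)


@pytest.fixture
def fast_config():
    """Registration settings sized for 64-px test fixtures."""
    return cw.RegistrationConfig(
        gamma1=1e-2, gamma2=1e-3,
        spacing_r1=8.0, spacing_r2=8.0, spacing_rp=8.0,
        grid_spacing_rp=12.0, grid_map_order=2,
        optimizer=cw.OptimizerConfig(max_iters=150),
    )
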