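import numpy as np
import pytest

from rsomskin import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid_shape():
    """A compact grid: 360 µm deep, 0.48 × 0.29 mm laterally (tests that do
    not need the full 1.5 mm dermis warn-free)."""
    return (120, 40, 24)


def make_flat_phantom(grid_shape=(300, 60, 40), surface_um=120.0,
                      thickness_um=105.0, vessels=(), noise_sigma=0.0,
                      psf_sigma_um=(0.0, 0.0, 0.0), seed=0, **kw):
    """Convenience wrapper: flat-surface phantom, no blur/noise by default."""
    spec = phantom.PhantomSpec(
        grid_shape=grid_shape, surface_depth_um=surface_um,
        ep_thickness_um=thickness_um, vessels=list(vessels),
        noise_sigma=noise_sigma, psf_sigma_um=psf_sigma_um, seed=seed, **kw)
    return phantom.make_skin_phantom(spec)


@pytest.fixture
def flat_phantom():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_flat_phantom()
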