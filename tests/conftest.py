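import numpy as np
import pytest

from petcoreg.geometry import ImageGeometry, Volume
from petcoreg.phantoms import PhantomSpec, generate_phantom
from petcoreg.segmentation import voi_around_point


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_volume(rng):
    """Small random PET-like volume on an anisotropic grid."""
    g = ImageGeometry(shape=(12, 10, 8), spacing=(4.1, 4.1, 5.0), origin=(-20.0, -15.0, -10.0))
    return Volume(geometry=g, values=rng.random(g.shape) * 10.0)


@pytest.fixture
def blurred_sphere():
    """Noise-free blurred sphere phantom with VOI and ground truth (2 mm grid)."""

    def factory(radius_mm=9.0, background_suv=1.0, lesion_suv=8.0, noise_sd=0.0, seed=0):
        margin = 25.0
        n = int(round(2 * (radius_mm + margin) / 2.0))
        g = ImageGeometry(
            shape=(n, n, n), spacing=(2.0, 2.0, 2.0),
            origin=(-(n - 1) * 1.0,) * 3,
        )
        spec = PhantomSpec.sphere(
            radius_mm, background_suv=background_suv, lesion_suv=lesion_suv,
            psf_fwhm=5.0, noise_sd=noise_sd, seed=seed,
        )
        vol, truth = generate_phantom(spec, g)
        voi = voi_around_point(g, (0.0, 0.0, 0.0), (radius_mm + 18.0,) * 3)
        return vol, voi, truth

    return factory
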