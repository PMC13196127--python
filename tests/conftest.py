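"""Shared fixtures: small phantoms and masks every module test reuses."""

import numpy as np
import pytest

from fracaug import (
    BinaryMask,
    DeformParams,
    DisplacementField,
    ImageVolume,
    IntensityModel,
    PhantomSpec,
    make_phantom,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(grid_shape=(64, 64, 48), spacing_mm=(2.0, 2.0, 2.0), seed=7)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """Default 9-organ phantom (image, labels)."""
    return make_phantom(phantom_spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and bias-free phantom for intensity-exact checks."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 32),
        intensity_model=IntensityModel(noise_std=0.0, bias_amplitude=0.0),
        seed=3,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_mask():
    """Isolated ellipsoid on a 1 mm grid, for sub-voxel recovery oracles."""
    shape = (64, 64, 64)
    coords = np.indices(shape, dtype=float)
    centre = np.array([32.0, 32.0, 32.0])
    semi = np.array([14.0, 12.0, 10.0])
    inside = sum(((coords[a] - centre[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0
    return BinaryMask(voxels=inside, spacing_mm=(1.0, 1.0, 1.0))


@pytest.fixture
def default_params():
    return DeformParams()


def constant_field(shape, translation_mm, spacing_mm=(2.0, 2.0, 2.0)):
    vectors = np.broadcast_to(np.asarray(translation_mm, dtype=float),
                              tuple(shape) + (3,)).copy()
    return DisplacementField(vectors=vectors, spacing_mm=spacing_mm)


def smooth_random_image(shape=(32, 32, 32), seed=0, spacing_mm=(2.0, 2.0, 2.0)):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    values = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    return ImageVolume(values=values, spacing_mm=spacing_mm)


def smooth_random_field(shape=(32, 32, 32), seed=0, amplitude=4.0,
                        spacing_mm=(2.0, 2.0, 2.0)):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    vectors = ndimage.gaussian_filter(
        rng.normal(0.0, amplitude, size=tuple(shape) + (3,)), (5, 5, 5, 0))
    return DisplacementField(vectors=vectors, spacing_mm=spacing_mm)
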