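import numpy as np
import pytest

from hemiacm.phantom import (
    MAX_POPULATIONS,
    OrientationField,
    build_phantom,
    default_phantom_spec,
    grid_affine,
    hemisphere_labels,
)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale two-bundle phantom used across unit tests."""
    return default_phantom_spec(grid_shape=(20, 20, 20))


@pytest.fixture(scope="session")
def small_build(small_spec):
    return build_phantom(small_spec)


def make_column_field(shape=(8, 8, 8), column=(1, 4), amplitude=0.8, voxel=2.0):
    """Hand-built single-fiber 1x1xNz column along z in the left hemisphere."""
    affine = grid_affine(shape, (voxel,) * 3)
    dirs = np.zeros(shape + (MAX_POPULATIONS, 3))
    amps = np.zeros(shape + (MAX_POPULATIONS,))
    wm = np.zeros(shape, dtype=bool)
    x, y = column
    wm[x, y, :] = True
    dirs[x, y, :, 0] = (0.0, 0.0, 1.0)
    amps[x, y, :, 0] = amplitude
    field = OrientationField(
        directions=dirs,
        amplitudes=amps,
        wm_mask=wm,
        hemisphere_labels=hemisphere_labels(shape),
        voxel_size=np.array([voxel] * 3),
        affine=affine,
    )
    field.validate()
    return field


@pytest.fixture()
def column_field():
    return make_column_field()
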