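import numpy as np
import pytest

from tuberhsi.cube_io import CubeKind, Hypercube, build_wavelength_axis
from tuberhsi.synthetic_data import DEFAULT_CULTIVARS, SliceSpec, generate_slice


@pytest.fixture
def axis():
    """The instrument grid: 256 bands, 900-1700 nm."""
    return build_wavelength_axis(900.0, 1700.0, 256)


@pytest.fixture
def rng():
    return np.random.default_rng(20161001)


@pytest.fixture
def small_spec():
    """Down-scaled slice geometry for fast unit tests."""
    return SliceSpec(
        shape=(48, 64),
        semi_axes=(14.0, 16.0),
        semi_axes_jitter_px=1.0,
        center_jitter_px=1.0,
    )


@pytest.fixture
def small_slice(small_spec, axis, rng):
    """One generated cooking-class slice at reduced size."""
    return generate_slice(small_spec, DEFAULT_CULTIVARS[0], axis, rng, "test_slice")


def make_cube(data, axis=None, kind=CubeKind.REFLECTANCE):
    data = np.asarray(data, dtype=float)
    if axis is None:
        axis = build_wavelength_axis(1000.0, 1000.0 + 10 * (data.shape[2] - 1), data.shape[2])
    return Hypercube(data, axis, kind)
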