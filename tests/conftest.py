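import numpy as np
import pytest

from arcdmd import ImageGrid, PhantomSpec, make_phantom
from arcdmd.phantom import params_for_volume


def small_grid(shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0)) -> ImageGrid:
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, float)
    origin = -(shape - 1) / 2.0 * spacing
    return ImageGrid(np.zeros(tuple(shape)), tuple(spacing), tuple(origin))


def random_dose_masks(rng, shape=(16, 16, 16), spacing=(3.0, 3.0, 3.0)):
    """Random dose grid with random (non-degenerate) ptv/body/lung masks.

    The PTV is confined to a central blob so tissue >= 2 cm away exists.
    """
    grid = small_grid(shape, spacing)
    dose = rng.gamma(2.0, 25.0, size=tuple(shape))
    body = rng.random(shape) < 0.8
    ptv = np.zeros(shape, dtype=bool)
    ptv[6:10, 6:10, 6:10] = rng.random((4, 4, 4)) < 0.6
    lung = (rng.random(shape) < 0.4) & body
    itv = ptv & (rng.random(shape) < 0.5)
    # guarantee non-emptiness
    body[8, 8, 8] = True
    ptv[8, 8, 8] = True
    body |= ptv
    lung[4, 4, 4] = True
    body[4, 4, 4] = True
    return grid, dose, ptv, body, lung, itv


@pytest.fixture(scope="session")
def coarse_sphere():
    """A small spherical-target phantom on the coarse preset."""
    spec = PhantomSpec.preset(
        "coarse", tumor_shape="sphere", tumor_params=params_for_volume("sphere", 8.0)
    )
    grid, structures = make_phantom(spec)
    return spec, grid, structures


@pytest.fixture(scope="session")
def coarse_ellipsoid():
    """Cranio-caudally elongated (3:1) ellipsoid target, coarse preset."""
    spec = PhantomSpec.preset(
        "coarse",
        tumor_shape="ellipsoid",
        tumor_params=params_for_volume("ellipsoid", 20.0, {"qa": 1, "qb": 1, "qc": 3}),
    )
    grid, structures = make_phantom(spec)
    return spec, grid, structures
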