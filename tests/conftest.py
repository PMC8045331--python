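import numpy as np
import pytest

from ctvmargins import BinaryVolume, PhantomSpec, make_phantom


def cube_volume(n: int, spacing: float = 1.0, origin: float = 0.0) -> BinaryVolume:
    """An all-foreground n^3 volume on an isotropic grid."""
    return BinaryVolume(
        np.ones((n, n, n), dtype=bool),
        np.full(3, float(spacing)),
        np.full(3, float(origin)),
    )


def embedded_cube(grid_n: int, cube_n: int, spacing: float = 1.0) -> BinaryVolume:
    """A cube_n^3 foreground block centered inside a grid_n^3 background grid."""
    occ = np.zeros((grid_n, grid_n, grid_n), dtype=bool)
    lo = (grid_n - cube_n) // 2
    occ[lo : lo + cube_n, lo : lo + cube_n, lo : lo + cube_n] = True
    return BinaryVolume(occ, np.full(3, float(spacing)), np.zeros(3))


@pytest.fixture(scope="session")
def slab_phantom():
    """10 mm slab GTV with +7 mm / -2 mm analytic x expansions on a 1 mm grid."""
    return make_phantom(
        PhantomSpec(
            gtv_shape="slab",
            size_mm=(10.0,),
            expansion={"per_face": {"+x": 7.0, "-x": 2.0}},
            spacing_mm=(1.0, 1.0, 1.0),
        )
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    """Sphere GTV r=10 mm with a 5 mm isotropic analytic expansion, 0.5 mm grid."""
    return make_phantom(
        PhantomSpec(gtv_shape="sphere", size_mm=(10.0,), expansion={"isotropic": 5.0})
    )


@pytest.fixture(scope="session")
def u_phantom():
    """Concave U-shaped GTV inside a generously expanded box CTV."""
    return make_phantom(
        PhantomSpec(
            gtv_shape="u_shape",
            size_mm=(20.0, 16.0, 8.0, 6.0, 10.0),
            expansion={"isotropic": 4.0},
        )
    )


@pytest.fixture(scope="session")
def small_sphere_phantom():
    """Coarse sphere phantom (1 mm grid) for tests that cast many ensembles."""
    return make_phantom(
        PhantomSpec(
            gtv_shape="sphere",
            size_mm=(10.0,),
            expansion={"isotropic": 7.0},
            spacing_mm=(1.0, 1.0, 1.0),
            padding_mm=8.0,
        )
    )
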