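import numpy as np
import pytest

from sparsecbct.geometry import ScanGeometry, generate_view_angles
from sparsecbct.phantoms import (GridSpec, MU_WATER, PhantomSpec, Primitive,
                                 build_rigid_anatomy)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale geometry with a small detector for fast unit tests."""
    return ScanGeometry().scaled(0.25)  # 128x128 panel, 3.2 mm pitch


@pytest.fixture(scope="session")
def sphere_spec():
    grid = GridSpec.cube(96, 2.0)
    prim = Primitive("ellipsoid", (10.0, -5.0, 3.0), (60.0, 60.0, 60.0), MU_WATER)
    return PhantomSpec("sphere", [prim], grid)


@pytest.fixture(scope="session")
def sphere_volume(sphere_spec):
    return sphere_spec.voxelize(supersample=2)


@pytest.fixture(scope="session")
def head_volume():
    """Head anatomy on a coarse grid (fast registration fixtures)."""
    return build_rigid_anatomy("head", seed=1, grid=GridSpec.cube(80, 2.5))


@pytest.fixture(scope="session")
def cylinder_stack(small_geometry):
    """Noiseless analytic projections of a uniform cylinder, 60 views."""
    from sparsecbct.projector import forward_project_analytic

    grid = GridSpec.cube(64, 3.125)
    spec = PhantomSpec(
        "cyl", [Primitive("cylinder", (0, 0, 0), (80.0, 80.0, 80.0), MU_WATER)],
        grid,
    )
    angles = generate_view_angles(small_geometry, 60)
    return spec, forward_project_analytic(spec, small_geometry, angles)
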