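"""Shared fixtures: physics database, desk geometry, cylinder scans.

The expensive session fixtures (360-view cylinder scans and their FDK
reconstructions, the desk-scale end-to-end training run) are shared between
the unit tests and the acceptance tests so each is computed once.
"""

import numpy as np
import pytest

from vmono import physics as P
from vmono.phantoms import make_cylinder_phantom
from vmono.projector import Geometry, project_mono, project_poly
from vmono.recon import GridSpec, fdk_reconstruct


@pytest.fixture(scope="session")
def db():
    return P.get_db()


@pytest.fixture(scope="session")
def water():
    return P.tissue("water")


@pytest.fixture(scope="session")
def desk_geometry():
    return Geometry.desk(64, 0.7)


@pytest.fixture(scope="session")
def water_cylinder():
    """d=10 mm water cylinder along the rotation axis, 64^3 at 0.28 mm."""
    return make_cylinder_phantom(10.0, 16.0, P.tissue("water"), (0, 0, 1),
                                 shape=(64, 64, 64),
                                 voxel_size=(0.28, 0.28, 0.28))


@pytest.fixture(scope="session")
def full_scan_angles():
    return np.arange(360.0)


@pytest.fixture(scope="session")
def cylinder_mono_scan(water_cylinder, desk_geometry, full_scan_angles):
    return project_mono(water_cylinder, desk_geometry, 35.0, full_scan_angles)


@pytest.fixture(scope="session")
def cylinder_poly_scan(water_cylinder, desk_geometry, full_scan_angles):
    return project_poly(water_cylinder, desk_geometry, P.imaging_spectrum(),
                        angles=full_scan_angles)


@pytest.fixture(scope="session")
def recon_grid():
    return GridSpec.desk(64, 0.25)


@pytest.fixture(scope="session")
def cylinder_mono_recon(cylinder_mono_scan, recon_grid):
    return fdk_reconstruct(cylinder_mono_scan, recon_grid)


@pytest.fixture(scope="session")
def cylinder_poly_recon(cylinder_poly_scan, recon_grid):
    return fdk_reconstruct(cylinder_poly_scan, recon_grid)


@pytest.fixture(scope="session")
def roi_coords(cylinder_mono_recon):
    vol = cylinder_mono_recon
    xs = vol.voxel_centers_mm(0)
    ys = vol.voxel_centers_mm(1)
    zs = vol.voxel_centers_mm(2)
    return np.meshgrid(xs, ys, zs, indexing="ij")


@pytest.fixture(scope="session")
def end_to_end_result():
    """The desk-scale simulate/train/evaluate run (shared, expensive)."""
    from vmono.pipeline import run_end_to_end

    return run_end_to_end(seed=1)
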