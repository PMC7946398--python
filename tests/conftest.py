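"""Shared fixtures: a small benchmark system reused across test modules.

The small bench (64x64 grid, 90 views, 96 channels) keeps sparse-operator
builds and iterative solves cheap; session scope means each expensive
artifact (system matrix, calibrated fluence, benchmark sinograms) is built
once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from cacstudy import fanbeam_sim, phantom_forge, recon_fbp
from cacstudy.phantom_forge import GridSpec, MaterialModel


@pytest.fixture(scope="session")
def materials():
    return MaterialModel()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(nx=64, ny=64, nz=2, dx=1.5, dy=1.5, dz=1.5)


@pytest.fixture(scope="session")
def small_geometry():
    # enough channels to keep detector-undersampling streaks well below the
    # quantum noise levels the bench tests probe
    return fanbeam_sim.desk_geometry(n_channels=192, n_views=120)


@pytest.fixture(scope="session")
def small_phantom(small_grid, materials):
    return phantom_forge.build_cardiac_rod(
        phantom_forge.study_inserts(), small_grid, materials
    )


@pytest.fixture(scope="session")
def small_epoxy(small_grid, materials):
    return phantom_forge.build_epoxy_rod(small_grid, materials)


@pytest.fixture(scope="session")
def small_ideal_sinogram(small_phantom, small_geometry):
    grid = small_phantom.grid
    return fanbeam_sim.project(small_phantom.mu[0], small_geometry, (grid.dy, grid.dx))


@pytest.fixture(scope="session")
def small_i0(small_phantom, small_geometry):
    """Fluence calibrated so 15-frame FBP noise is ~7.4 HU on the small bench."""
    return fanbeam_sim.calibrate_i0(
        7.4, small_phantom, small_geometry, recon_fbp.FbpKernel(), seed=20240915
    )


@pytest.fixture(scope="session")
def small_lnp_sinogram(small_ideal_sinogram, small_geometry, small_i0):
    stack = fanbeam_sim.simulate_counts(small_ideal_sinogram, small_i0, 15, 42)
    return fanbeam_sim.average_and_log(stack, small_geometry)


@pytest.fixture(scope="session")
def small_background_roi(small_phantom):
    return small_phantom.background_mask()[0]


def antialiased_disk(grid, radius: float, mu0: float, n: int = 5):
    """Disk with supersampled partial-volume edge (for projector oracles)."""
    x, y, _ = grid.axis_coords()
    off = (np.arange(n) - (n - 1) / 2.0) / n
    frac = np.zeros((grid.ny, grid.nx))
    for oy in off:
        for ox in off:
            xx, yy = np.meshgrid(x + ox * grid.dx, y + oy * grid.dy)
            frac += xx**2 + yy**2 <= radius**2
    return mu0 * frac / n**2
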