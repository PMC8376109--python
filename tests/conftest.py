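"""Shared fixtures: small phantoms, grids and traces sized for fast tests."""

import numpy as np
import pytest

from xepcv.breath import synthetic_inhalation_trace
from xepcv.grids import DynamicWindow, sagittal_slab_grid
from xepcv.phantom import AnalyticFlowField, TubePhantom


class StubField:
    """Analytic-field stand-in with a prescribed velocity function.

    Mimics the ``AnalyticFlowField`` surface (``phantom``, ``velocity``,
    ``velocity_series``) for resampling tests that need exactly known voxel
    averages (constant or linear fields), which no physical tube flow
    provides.
    """

    def __init__(self, phantom, func):
        self.phantom = phantom
        self.func = func  # (points (N,3) m, t) -> (N,3) m/s
        self.support = (-np.inf, np.inf)

    def velocity(self, points_m, t):
        return self.func(np.atleast_2d(points_m), t)

    def velocity_series(self, points_m, times, out=None):
        p = np.atleast_2d(points_m)
        if out is None:
            out = np.zeros((len(times), len(p), 3))
        for i, t in enumerate(times):
            out[i] = self.func(p, float(t))
        return out


@pytest.fixture(scope="session")
def tube():
    return TubePhantom()  # radius 7.5 mm, length 0.2 m, xenon


@pytest.fixture(scope="session")
def everywhere_phantom():
    """A tube so wide that every test grid voxel is fully inside the lumen."""
    return TubePhantom(radius=1.0, length=2.0, z_low=-1.0)


@pytest.fixture(scope="session")
def steady_field(tube):
    return AnalyticFlowField(tube, 8.0e-5, mode="steady")


@pytest.fixture(scope="session")
def small_grid():
    # slab 20 mm spans the full 15 mm tube diameter
    return sagittal_slab_grid(
        fov_ap_mm=30.0, fov_fh_mm=40.0, in_plane_mm=1.25, slab_mm=20.0
    )


@pytest.fixture(scope="session")
def window():
    return DynamicWindow(0.0, 3.1)


@pytest.fixture(scope="session")
def breath_trace():
    return synthetic_inhalation_trace()


@pytest.fixture
def stub_constant(everywhere_phantom):
    """Uniform 0.5 m/s foot-head velocity everywhere."""

    def func(p, t):
        v = np.zeros((len(p), 3))
        v[:, 2] = 0.5
        return v

    return StubField(everywhere_phantom, func)


@pytest.fixture
def stub_linear(everywhere_phantom):
    """Foot-head velocity linear in the axial coordinate: u = 3·z + 0.1."""

    def func(p, t):
        v = np.zeros((len(p), 3))
        v[:, 2] = 3.0 * p[:, 2] + 0.1
        return v

    return StubField(everywhere_phantom, func)
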