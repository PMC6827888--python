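"""Shared fixtures: small meshes and converged flow solves, built once."""

import numpy as np
import pytest
from hypothesis import settings

import cytoconvect as cc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

T_BODY = 310.15  # 37 °C in Kelvin


@pytest.fixture(scope="session")
def props():
    return cc.FluidProperties()


@pytest.fixture(scope="session")
def geom2d():
    """Default 2-D cell: R = 10 μm disc, r = 4.3 μm nucleus offset 2 μm."""
    return cc.spherical_cell_geometry(dimension=2)


@pytest.fixture(scope="session")
def geom2d_concentric():
    return cc.spherical_cell_geometry(dimension=2, offset=0.0)


@pytest.fixture(scope="session")
def mesh2d(geom2d):
    return cc.build_spherical_cell(geom2d, target_edge_length=0.45)


@pytest.fixture(scope="session")
def mesh2d_concentric(geom2d_concentric):
    return cc.build_spherical_cell(geom2d_concentric, target_edge_length=0.45)


@pytest.fixture(scope="session")
def geom3d():
    return cc.spherical_cell_geometry(dimension=3)


@pytest.fixture(scope="session")
def mesh3d_coarse(geom3d):
    """Coarse 3-D shell (≈1 000 nodes) for fast qualitative 3-D checks."""
    return cc.build_spherical_cell(geom3d, subdivisions=2, n_radial=5)


@pytest.fixture(scope="session")
def flow2d_heated(mesh2d, props):
    """ΔT = 1 °C (nucleus 38 °C, membrane 37 °C) on the default 2-D cell."""
    return cc.solve_flow(mesh2d, props, cc.ThermalBC(T_BODY, T_BODY + 1.0))


@pytest.fixture(scope="session")
def flow2d_quiescent(mesh2d, props):
    return cc.solve_flow(mesh2d, props, cc.ThermalBC(T_BODY, T_BODY))


@pytest.fixture(scope="session")
def flow3d_heated_coarse(mesh3d_coarse, props):
    return cc.solve_flow(mesh3d_coarse, props, cc.ThermalBC(T_BODY, T_BODY + 1.0))


@pytest.fixture(scope="session")
def flow3d_quiescent_coarse(mesh3d_coarse, props):
    return cc.solve_flow(mesh3d_coarse, props, cc.ThermalBC(T_BODY, T_BODY))
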