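"""Shared fixtures: all geometry is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import prostmould as pm


def make_sphere(radius=10.0, center=(0.0, 0.0, 0.0), subdivisions=4,
                name="sphere") -> pm.SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return pm.SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center, float),
                          np.asarray(tm.faces), source_name=name)


def make_cube(extent=1.0, center=(0.5, 0.5, 0.5)) -> pm.SurfaceMesh:
    tm = trimesh.creation.box(extents=[extent] * 3)
    return pm.SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center, float),
                          np.asarray(tm.faces), source_name="cube")


@pytest.fixture(scope="session")
def sphere10() -> pm.SurfaceMesh:
    return make_sphere(10.0)


@pytest.fixture(scope="session")
def phantom_one() -> pm.PhantomCase:
    """Default ellipsoid prostate with one off-centre spherical ROI."""
    spec = pm.PhantomSpec(
        roi_specs=[pm.RoiSpec("roi_1", (5.0, -3.0, 4.0), radius_mm=5.0)],
        seed=1)
    return pm.generate_phantom(spec)


@pytest.fixture(scope="session")
def coarse_spec() -> pm.MouldSpec:
    """Coarser extraction pitch for unit tests (accuracy checked elsewhere)."""
    return pm.MouldSpec(grid_pitch_mm=0.6)


@pytest.fixture(scope="session")
def phantom_small() -> pm.PhantomCase:
    """Lower-resolution phantom for tests that build full moulds."""
    spec = pm.PhantomSpec(
        roi_specs=[pm.RoiSpec("roi_1", (5.0, -3.0, 4.0), radius_mm=5.0)],
        mesh_resolution=3, seed=1)
    return pm.generate_phantom(spec)


@pytest.fixture(scope="session")
def mould_variants(phantom_small, coarse_spec) -> list[pm.MouldModel]:
    return pm.build_mould_variants(phantom_small.case, coarse_spec)
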