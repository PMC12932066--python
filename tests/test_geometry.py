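"""Geometry core: rasterisation parity, exact distances, SDF extraction,
ray/segment clipping.  Oracles are closed forms and brute-force sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prostmould as pm
from prostmould import rasterize, raycast, sdf

from conftest import make_sphere


# ---------------------------------------------------------------- rasterize

def test_occupancy_parity_volume_matches_mesh_volume(sphere10):
    pitch = 0.4
    origin, shape = rasterize.grid_for_bounds(sphere10.bounds, pitch)
    occ = rasterize.occupancy_grid(sphere10.vertices, sphere10.faces,
                                   origin, pitch, shape)
    voxel_volume = occ.sum() * pitch**3
    assert voxel_volume == pytest.approx(sphere10.volume_mm3, rel=0.01)


def test_column_crossings_always_even(sphere10):
    """Watertight surface => every grid column crosses it an even number of
    times, even where columns graze shared edges or vertices."""
    pitch = 0.5
    origin, shape = rasterize.grid_for_bounds(sphere10.bounds, pitch)
    gi, gj, _ = rasterize.column_crossings(
        sphere10.vertices, sphere10.faces, origin[:2], pitch,
        shape[0], shape[1])
    cols, counts = np.unique(np.stack([gi, gj]), axis=1, return_counts=True)
    assert (counts % 2 == 0).all()


def test_point_triangle_distance_against_dense_sampling():
    rng = np.random.default_rng(11)
    tris = rng.normal(size=(60, 3, 3)) * 5.0
    pts = rng.normal(size=(60, 3)) * 6.0
    exact = rasterize.point_triangle_distance(pts, tris)
    # brute force: dense barycentric sampling of each triangle
    n = 120
    u, v = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n))
    keep = (u + v) <= 1.0
    u, v = u[keep], v[keep]
    bary = np.stack([1 - u - v, u, v], axis=1)
    for i in range(len(tris)):
        samples = bary @ tris[i]
        brute = np.linalg.norm(samples - pts[i], axis=1).min()
        assert exact[i] <= brute + 1e-12
        assert exact[i] == pytest.approx(brute, abs=0.05)


def test_signed_distance_grid_matches_analytic_sphere(sphere10):
    pitch = 0.4
    origin, shape = rasterize.grid_for_bounds(sphere10.bounds, pitch)
    grid = rasterize.signed_distance_grid(sphere10.vertices, sphere10.faces,
                                          origin, pitch, shape, band=3.0)
    pts = rasterize.grid_points(origin, pitch, shape)
    analytic = np.linalg.norm(pts, axis=1).reshape(shape) - 10.0
    band = np.abs(analytic) < 2.5
    # icosphere deviates from the ball by < 0.04 mm at 4 subdivisions
    assert np.abs(grid[band] - analytic[band]).max() < 0.05


# ----------------------------------------------------------------- sdf/CSG

def test_primitive_sdf_values():
    box = sdf.Box(np.array([[0.0, 0, 0], [2.0, 2, 2]]))
    assert box(np.array([[1.0, 1, 1]]))[0] == pytest.approx(-1.0)
    assert box(np.array([[3.0, 1, 1]]))[0] == pytest.approx(1.0)
    cyl = sdf.Cylinder((0, 0, 0), (0, 0, 10), radius=2.0)
    assert cyl(np.array([[0.0, 0, 5]]))[0] == pytest.approx(-2.0)
    assert cyl(np.array([[5.0, 0, 5]]))[0] == pytest.approx(3.0)
    assert cyl(np.array([[0.0, 0, 12]]))[0] == pytest.approx(2.0)


def test_extraction_reproduces_sphere_and_offsets(sphere10):
    mesh_field = sdf.MeshSDF(sphere10, band=4.0)
    for level, r in [(0.0, 10.0), (1.0, 11.0)]:
        out = sdf.extract_surface(mesh_field, sphere10.bounds, 0.4,
                                  level=level)
        assert out.as_trimesh().is_watertight
        assert out.volume_mm3 == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)


def test_csg_difference_volume():
    """Box minus analytic sphere: volumes subtract (closed forms)."""
    box = sdf.Box(np.array([[-20.0, -20, -20], [20.0, 20, 20]]))
    ball = sdf.Cylinder((0, 0, -10), (0, 0, 10), 10.0)  # cylinder r=10 h=20
    out = sdf.extract_surface(box.difference(ball),
                              np.array([[-20.0, -20, -20], [20.0, 20, 20]]),
                              0.4)
    expected = 40.0**3 - np.pi * 100.0 * 20.0
    assert out.volume_mm3 == pytest.approx(expected, rel=0.01)


def test_extruded_polygon_prism_volume():
    import shapely

    square = shapely.box(-5, -5, 5, 5)
    prism = sdf.ExtrudedPolygon(square, axis=2, lo=0.0, hi=8.0)
    out = sdf.extract_surface(prism,
                              np.array([[-6.0, -6, -1], [6.0, 6, 9]]), 0.3)
    assert out.volume_mm3 == pytest.approx(10 * 10 * 8, rel=0.01)


def test_empty_isosurface_raises():
    box = sdf.Box(np.array([[0.0, 0, 0], [1.0, 1, 1]]))
    with pytest.raises(pm.BooleanError):
        sdf.extract_surface(box, np.array([[10.0, 10, 10], [11.0, 11, 11]]),
                            0.3)


# ----------------------------------------------------------------- raycast

def test_line_crossings_chord_lengths(sphere10):
    spans = raycast.inside_intervals((0, 0, -30), (0, 0, 1),
                                     sphere10.vertices, sphere10.faces)
    assert len(spans) == 1
    assert spans[0][1] - spans[0][0] == pytest.approx(20.0, rel=0.01)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(offset=st.floats(min_value=0.0, max_value=14.0))
def test_segment_chords_match_circle_formula(offset):
    """Chord of a sphere at lateral offset h: 2*sqrt(r^2-h^2), 0 outside."""
    sphere = make_sphere(10.0, subdivisions=3)
    length = raycast.segment_inside_length((offset, -40.0, 0.0),
                                           (offset, 40.0, 0.0),
                                           sphere.vertices, sphere.faces)
    if offset >= 10.0:
        assert length == 0.0
    else:
        expected = 2.0 * np.sqrt(100.0 - offset**2)
        assert length == pytest.approx(expected, abs=0.25)


def test_batched_segments_agree_with_single(sphere10):
    rng = np.random.default_rng(5)
    p0 = rng.normal(size=(40, 3)) * 15.0
    p1 = rng.normal(size=(40, 3)) * 15.0
    batch = raycast.segments_inside_length(p0, p1, sphere10.vertices,
                                           sphere10.faces)
    singles = [raycast.segment_inside_length(a, b, sphere10.vertices,
                                             sphere10.faces)
               for a, b in zip(p0, p1)]
    assert np.allclose(batch, singles, atol=1e-9)


def test_points_inside_ellipsoid():
    mesh = pm.generate_phantom(pm.PhantomSpec(
        roi_specs=[pm.RoiSpec("r", (0, 0, 0), radius_mm=4.0)],
        seed=0)).boundary
    rng = np.random.default_rng(2)
    pts = rng.uniform(-25, 25, size=(120, 3))
    semi = np.array([20.0, 18.0, 22.0])
    analytic = (np.sum((pts / semi) ** 2, axis=1) < 1.0)
    got = raycast.points_inside(pts, mesh.vertices, mesh.faces)
    # disagreement possible only within the facet sagitta of the surface
    close = np.abs(np.sum((pts / semi) ** 2, axis=1) - 1.0) < 0.02
    assert (got[~close] == analytic[~close]).all()
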