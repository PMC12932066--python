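"""Guide planning: centres of mass, approach choice, length calibration and
channel carving."""

import numpy as np
import pytest

import prostmould as pm
from prostmould import rasterize, sdf
from prostmould.guides import (calibrate_guide, carve_guides,
                               check_channel_collisions, choose_approaches)
from prostmould.mould import build_block

from conftest import make_cube, make_sphere

BLOCK = np.array([[-20.0, -20.0, -20.0], [20.0, 20.0, 20.0]])


def test_center_of_mass_symmetric_shapes():
    sphere = make_sphere(6.0, center=(10.0, 20.0, 30.0), subdivisions=3)
    assert np.linalg.norm(pm.center_of_mass(sphere) - (10, 20, 30)) < 1e-3
    cube = make_cube(extent=1.0, center=(0.5, 0.5, 0.5))
    assert np.allclose(pm.center_of_mass(cube), (0.5, 0.5, 0.5), atol=1e-12)


def test_center_of_mass_requires_closed_surface():
    cube = make_cube()
    with pytest.raises(pm.MeshValidationError):
        pm.center_of_mass(pm.SurfaceMesh(cube.vertices, cube.faces[:-1]))


def test_center_of_mass_two_sphere_union_vs_voxel_oracle():
    """Merged asymmetric two-sphere solid: centroid against a fine voxel
    centroid (independent occupancy-counting route)."""
    a = make_sphere(5.0, (0, 0, 0), subdivisions=3)
    b = make_sphere(3.0, (6.0, 0, 0), subdivisions=3)  # overlapping
    union = sdf.MeshSDF(a, band=3.0).union(sdf.MeshSDF(b, band=3.0))
    merged = sdf.extract_surface(
        union, np.array([[-6.0, -6, -6], [10.0, 6, 6]]), 0.25)
    centroid = pm.center_of_mass(merged)

    pitch = 0.2
    origin, shape = rasterize.grid_for_bounds(merged.bounds, pitch, pad=1.0)
    occ = rasterize.occupancy_grid(merged.vertices, merged.faces, origin,
                                   pitch, shape)
    idx = np.argwhere(occ)
    voxel_centroid = origin + pitch * idx.mean(axis=0)
    assert np.linalg.norm(centroid - voxel_centroid) < 0.1


def test_choose_approaches_tie_break_and_ordering():
    spec = pm.MouldSpec()
    # block centre: all four faces equidistant -> fixed tie-break order
    assert choose_approaches((0, 0, 0), BLOCK, spec) == ["superior",
                                                         "posterior"]
    # displaced toward the left (+x in LPS) face: left-lateral ranks first
    assert choose_approaches((15, 0, 0), BLOCK, spec)[0] == "left-lateral"
    spec.guides_per_roi = 5
    with pytest.raises(ValueError):
        choose_approaches((0, 0, 0), BLOCK, spec)


def test_calibration_identity_and_tower_height():
    spec = pm.MouldSpec()  # 14G manual: tip_to_notch_center = 0, depth 50
    # centroid 20 below the superior face (z=20): face distance 20, tower 30
    g = calibrate_guide((0, 0, 0), "superior", BLOCK, spec)
    assert g.tower_height_mm == pytest.approx(30.0)
    assert g.target_depth_mm == pytest.approx(50.0, abs=1e-9)
    # forward substitution: the needle tip at full insertion is the centroid
    tip = g.entry_point_mm + g.direction * spec.insertion_depth_mm
    assert np.linalg.norm(tip - g.target_point_mm) < 1e-6

    # exactly reachable: centroid 50 mm below the face -> zero tower
    g0 = calibrate_guide((0, 0, -30.0), "superior", BLOCK, spec)
    assert g0.tower_height_mm == pytest.approx(0.0)

    # unreachable target (60 mm deep) names the deficit
    big = np.array([[-20.0, -20, -40], [20.0, 20, 20]])
    with pytest.raises(pm.CalibrationError) as exc:
        calibrate_guide((0, 0, -40.0), "superior", big, spec)
    assert exc.value.deficit_mm == pytest.approx(10.0)


def test_fired_needle_notch_centre_lands_on_centroid():
    spec = pm.MouldSpec(needle=pm.BARD_18G)
    g = calibrate_guide((0, 0, 0), "superior", BLOCK, spec)
    assert g.target_depth_mm == pytest.approx(50.0 - 13.0, abs=1e-9)
    tip = g.entry_point_mm + g.direction * spec.insertion_depth_mm
    notch_center = tip - g.direction * spec.needle.tip_to_notch_center_mm
    assert np.linalg.norm(notch_center - g.target_point_mm) < 1e-6


def test_channel_collision_detection():
    spec = pm.MouldSpec()
    a = calibrate_guide((0, 0, 0), "superior", BLOCK, spec)
    b = calibrate_guide((1.0, 0, 0), "superior", BLOCK, spec)  # 1 mm apart
    a.channel_length_mm = b.channel_length_mm = 30.0
    a.channel_diameter_mm = b.channel_diameter_mm = 2.4
    with pytest.raises(pm.LayoutError) as exc:
        check_channel_collisions([a, b])
    assert "superior" in str(exc.value)


def test_carve_single_guide_volume_arithmetic(sphere10):
    """Carving removes the channel bore through the wall and adds the tower
    annulus; both have closed-form cylinder volumes."""
    spec = pm.MouldSpec(grid_pitch_mm=0.4)
    block = build_block(sphere10, 10.0)
    mould = pm.subtract_cavity(block, sphere10, pitch_mm=0.4)
    g = calibrate_guide((0, 0, 0), "superior", BLOCK, spec)
    carved = carve_guides(mould, [g], spec)
    assert carved.as_trimesh().is_watertight
    r_chan = g.channel_diameter_mm / 2.0
    r_tower = r_chan + spec.tower_wall_mm
    wall = 10.0  # block face z=20 to cavity surface z=10
    removed = np.pi * r_chan**2 * wall
    added = np.pi * (r_tower**2 - r_chan**2) * g.tower_height_mm
    expected = mould.volume_mm3 - removed + added
    assert carved.volume_mm3 - mould.volume_mm3 == pytest.approx(
        added - removed, rel=0.02)
    assert carved.volume_mm3 == pytest.approx(expected, rel=0.01)
    # channel stops at the cavity: recorded length = wall + tower
    assert g.channel_length_mm == pytest.approx(g.tower_height_mm + wall,
                                                abs=0.1)


def test_guides_per_roi_on_cohort():
    spec = pm.MouldSpec()
    for ph in pm.default_cohort_phantoms(4, seed=11, mesh_resolution=3):
        from prostmould.mould import plan_guides
        bounds = np.vstack([ph.boundary.bounds[0] - spec.wall_margin_mm,
                            ph.boundary.bounds[1] + spec.wall_margin_mm])
        guides = plan_guides(ph.case, spec, bounds)
        assert len(guides) == spec.guides_per_roi * len(ph.rois)
        for g in guides:
            assert abs(g.target_depth_mm - 50.0) < 1e-6
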