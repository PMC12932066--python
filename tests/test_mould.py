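"""Mould construction: offsets, block arithmetic, boolean subtraction,
insertion opening, and the full variant pipeline."""

import numpy as np
import pytest

import prostmould as pm
from prostmould import rasterize, raycast
from prostmould.mould import build_block, silhouette_polygon
from prostmould.voxel import voxel_mould_volume

from conftest import make_sphere


def test_offset_sphere_matches_closed_form(sphere10):
    out = pm.offset_surface(sphere10, 1.0, pitch_mm=0.4)
    assert out.volume_mm3 == pytest.approx(4 / 3 * np.pi * 11.0**3, rel=0.02)
    assert out.as_trimesh().is_watertight


def test_offset_zero_is_near_identity(phantom_small):
    out = pm.offset_surface(phantom_small.boundary, 0.0, pitch_mm=0.5)
    assert out.volume_mm3 == pytest.approx(phantom_small.boundary.volume_mm3,
                                           rel=0.005)


def test_offset_contains_input_vertices():
    ph = pm.generate_phantom(pm.PhantomSpec(
        roi_specs=[pm.RoiSpec("r", (0, 0, 0), radius_mm=4.0)],
        boundary_noise_mm=1.0, mesh_resolution=3, seed=3))
    out = pm.offset_surface(ph.boundary, 2.0, pitch_mm=0.5)
    inside = raycast.points_inside(ph.boundary.vertices, out.vertices,
                                   out.faces)
    assert inside.all()


def test_offset_rejects_negative_delta(sphere10):
    with pytest.raises(ValueError):
        pm.offset_surface(sphere10, -1.0)


def test_build_block_bbox_arithmetic(sphere10):
    block = build_block(sphere10, 10.0)
    assert np.allclose(block.bounds, [[-20, -20, -20], [20, 20, 20]])
    assert block.volume_mm3 == pytest.approx(40.0**3)

    ell = pm.generate_phantom(pm.PhantomSpec(
        roi_specs=[pm.RoiSpec("r", (0, 0, 0), radius_mm=4.0)],
        seed=0)).boundary
    block = build_block(ell, 10.0)
    sizes = block.bounds[1] - block.bounds[0]
    assert np.allclose(sizes, [60, 56, 64], atol=0.1)

    with pytest.raises(ValueError):
        build_block(sphere10, 2.0, min_wall_mm=3.0)


def test_subtract_cavity_volume_closed_form(sphere10):
    block = build_block(sphere10, 10.0)
    mould = pm.subtract_cavity(block, sphere10, pitch_mm=0.4)
    expected = 40.0**3 - 4 / 3 * np.pi * 1000.0
    assert mould.volume_mm3 == pytest.approx(expected, rel=0.01)
    assert mould.as_trimesh().is_watertight


def test_subtract_cavity_requires_strict_containment(sphere10):
    touching = make_sphere(10.0, center=(10.0, 0.0, 0.0))  # touches the face
    block = build_block(sphere10, 10.0)
    with pytest.raises(ValueError):
        pm.subtract_cavity(block, touching, pitch_mm=0.5)


def test_insertion_opening_area_and_monotonicity(sphere10):
    block = build_block(sphere10, 10.0)
    mould = pm.subtract_cavity(block, sphere10, pitch_mm=0.4)
    opened = pm.cut_insertion_opening(mould, sphere10, "anterior",
                                      pitch_mm=0.4)
    assert opened.volume_mm3 < mould.volume_mm3
    assert opened.as_trimesh().is_watertight
    # cross-section of the void at a plane between cavity and face (y=-15,
    # LPS anterior = -y) equals the sphere silhouette area pi r^2
    pitch = 0.25
    origin, shape = rasterize.grid_for_bounds(opened.bounds, pitch, pad=1.0)
    occ = rasterize.occupancy_grid(opened.vertices, opened.faces, origin,
                                   pitch, shape)
    j = int(round((-15.0 - origin[1]) / pitch))
    solid_area = occ[:, j, :].sum() * pitch**2
    block_area = 40.0 * 40.0
    assert block_area - solid_area == pytest.approx(np.pi * 100.0, rel=0.02)


def test_opening_rejected_on_approach_face(sphere10, coarse_spec):
    block = build_block(sphere10, 10.0)
    mould = pm.subtract_cavity(block, sphere10, pitch_mm=0.6)
    with pytest.raises(ValueError):
        pm.cut_insertion_opening(mould, sphere10, "superior", spec=coarse_spec)


def test_silhouette_area_of_sphere(sphere10):
    poly = silhouette_polygon(sphere10, axis=1)
    assert poly.area == pytest.approx(np.pi * 100.0, rel=0.01)


def test_variant_pipeline(mould_variants, phantom_small, coarse_spec):
    assert [m.variant_offset_mm for m in mould_variants] == [0.0, 1.0, 2.0]
    vols = [m.cavity_volume_mm3 for m in mould_variants]
    assert vols[0] < vols[1] < vols[2]
    for m in mould_variants:
        assert m.solid.as_trimesh().is_watertight
        assert len(m.guides) == coarse_spec.guides_per_roi * len(
            phantom_small.rois)
        checks = pm.verify_mould(m, phantom_small.boundary)
        assert checks["ok"], checks


def test_variant_solid_volume_matches_voxel_oracle(mould_variants,
                                                   phantom_small):
    m = mould_variants[1]
    oracle = voxel_mould_volume(phantom_small.boundary, m, pitch=0.5)
    assert m.solid_volume_mm3 == pytest.approx(oracle, rel=0.02)


def test_build_is_deterministic(phantom_small, coarse_spec, tmp_path):
    """Same case and spec twice: byte-identical STL exports."""
    again = pm.build_mould_variants(phantom_small.case, coarse_spec)
    a = tmp_path / "a.stl"
    b = tmp_path / "b.stl"
    first = pm.build_mould_variants(phantom_small.case, coarse_spec)
    pm.save_stl(first[0].solid, a)
    pm.save_stl(again[0].solid, b)
    assert a.read_bytes() == b.read_bytes()


def test_spec_invariants():
    with pytest.raises(ValueError):
        pm.MouldSpec(offsets_mm=(1.0, 1.0))
    with pytest.raises(ValueError):
        pm.MouldSpec(insertion_face="superior")
    with pytest.raises(ValueError):
        pm.MouldSpec(guides_per_roi=5)
    with pytest.raises(ValueError):
        pm.MouldSpec(wall_margin_mm=2.0)
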