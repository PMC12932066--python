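"""Mould construction: boundary offsetting, block creation, cavity
subtraction, specimen-insertion opening and the per-patient variant set.

A mould is a material-optimised rectangular block (the cavity's bounding box
plus a wall margin — "material-optimised" wins over a literal cube) from
which the prostate-shaped cavity, a specimen-insertion opening and the
needle-guide channels are subtracted.  Three variants are built per case,
with the cavity offset outward by 0, 1 and 2 mm to tolerate slight boundary
segmentation error; all three share one guide plan computed from the
unoffset boundary, so they target identically.

The specimen enters through an open face (default anterior, which no biopsy
approach uses): the subtracted opening is the cavity silhouette swept from
the cavity's axial midplane out through the block — the swept volume a rigid
specimen needs to slide into place.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Sequence

import numpy as np
import trimesh

import shapely

from . import raycast
from .cases import ProstateCase
from .errors import LayoutError
from .frames import face_axis
from .guides import (NeedleGuide, calibrate_guide, center_of_mass,
                     channel_end_depth, check_channel_collisions,
                     choose_approaches)
from .mesh_io import SurfaceMesh, validate
from .needles import TRUCUT_14G, NeedleModel
from .sdf import Box, Cylinder, ExtrudedPolygon, MeshSDF, extract_surface

#: Default surface-extraction grid pitch (mm): fine enough that re-sampled
#: solids keep volumes within a fraction of a percent, coarse enough that a
#: full variant set builds in well under a minute.
DEFAULT_PITCH_MM = 0.45


@dataclasses.dataclass
class MouldSpec:
    """All generation parameters for one patient's mould set."""

    wall_margin_mm: float = 10.0
    offsets_mm: Sequence[float] = (0.0, 1.0, 2.0)
    insertion_face: str = "anterior"
    needle: NeedleModel = TRUCUT_14G
    insertion_depth_mm: float = 50.0
    approaches: Sequence[str] = ("superior", "posterior",
                                 "left-lateral", "right-lateral")
    guides_per_roi: int = 2
    channel_clearance_mm: float = 0.25
    min_wall_mm: float = 3.0
    tower_wall_mm: float = 1.5
    grid_pitch_mm: float = DEFAULT_PITCH_MM

    def __post_init__(self):
        offs = list(self.offsets_mm)
        if any(o < 0 for o in offs) or any(
                b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("offsets_mm must be >= 0 and strictly increasing")
        if self.insertion_face in self.approaches:
            raise ValueError(
                f"insertion face {self.insertion_face!r} cannot also be a "
                f"biopsy approach")
        if self.guides_per_roi > len(self.approaches):
            raise ValueError("guides_per_roi exceeds the number of approaches")
        if self.guides_per_roi < 1:
            raise ValueError("guides_per_roi must be >= 1")
        if self.insertion_depth_mm <= 0:
            raise ValueError("insertion_depth_mm must be positive")
        if self.wall_margin_mm < self.min_wall_mm:
            raise ValueError(
                f"wall margin {self.wall_margin_mm} mm below the minimum "
                f"printable wall {self.min_wall_mm} mm")
        if self.wall_margin_mm - max(offs) < self.min_wall_mm:
            raise ValueError(
                "wall margin leaves less than min_wall after the largest "
                "cavity offset")


@dataclasses.dataclass
class MouldModel:
    """One printed variant: the carved solid plus its provenance."""

    case_id: str
    variant_offset_mm: float
    solid: SurfaceMesh
    cavity_surface: SurfaceMesh
    block_bounds: np.ndarray
    guides: list[NeedleGuide]
    spec: MouldSpec

    @property
    def solid_volume_mm3(self) -> float:
        return self.solid.volume_mm3

    @property
    def cavity_volume_mm3(self) -> float:
        return self.cavity_surface.volume_mm3


# --------------------------------------------------------------------------
# staged operations
# --------------------------------------------------------------------------

def offset_surface(mesh: SurfaceMesh, delta_mm: float,
                   pitch_mm: float = DEFAULT_PITCH_MM) -> SurfaceMesh:
    """Outward offset: the surface of points at signed distance ``delta`` mm.

    Implemented as the ``delta`` level set of the mesh's signed distance
    field; always watertight and self-intersection free (an SDF level set
    cannot self-intersect, unlike naive vertex-normal displacement).
    """
    if delta_mm < 0:
        raise ValueError("delta_mm must be >= 0 (outward offsets only)")
    validate(mesh)
    field = MeshSDF(mesh, band=delta_mm + 4.0)
    return extract_surface(field, mesh.bounds, pitch_mm, level=delta_mm,
                           frame_label=mesh.frame_label,
                           source_name=f"{mesh.source_name}+{delta_mm:g}mm")


def build_block(cavity: SurfaceMesh, wall_margin_mm: float,
                min_wall_mm: float = 3.0) -> SurfaceMesh:
    """Axis-aligned block: cavity bounding box grown by the wall margin."""
    if wall_margin_mm < min_wall_mm:
        raise ValueError(
            f"wall margin {wall_margin_mm} mm below minimum wall "
            f"{min_wall_mm} mm")
    bounds = cavity.bounds
    lo = bounds[0] - wall_margin_mm
    hi = bounds[1] + wall_margin_mm
    box = trimesh.creation.box(bounds=np.vstack([lo, hi]))
    return SurfaceMesh.from_trimesh(box, frame_label=cavity.frame_label,
                                    source_name="block")


def _require_strictly_inside(inner: SurfaceMesh, outer: SurfaceMesh,
                             eps: float = 1e-6):
    ib, ob = inner.bounds, outer.bounds
    if not ((ib[0] > ob[0] + eps).all() and (ib[1] < ob[1] - eps).all()):
        raise ValueError("cavity must lie strictly inside the block")
    sample = inner.vertices[:: max(1, len(inner.vertices) // 200)]
    if not raycast.points_inside(sample, outer.vertices, outer.faces).all():
        raise ValueError("cavity must lie strictly inside the block")


def subtract_cavity(block: SurfaceMesh, cavity: SurfaceMesh,
                    pitch_mm: float = DEFAULT_PITCH_MM) -> SurfaceMesh:
    """Boolean difference block minus cavity (watertight or error)."""
    _require_strictly_inside(cavity, block)
    field = MeshSDF(block).difference(MeshSDF(cavity))
    return extract_surface(field, block.bounds, pitch_mm,
                           frame_label=block.frame_label,
                           source_name="mould")


def silhouette_polygon(mesh: SurfaceMesh, axis: int):
    """Outline of the mesh's orthographic projection along ``axis``
    (a shapely polygon in the two remaining coordinates, natural order)."""
    other = [a for a in range(3) if a != axis]
    tris2 = mesh.vertices[mesh.faces][:, :, other]
    cross = ((tris2[:, 1, 0] - tris2[:, 0, 0]) * (tris2[:, 2, 1] - tris2[:, 0, 1])
             - (tris2[:, 1, 1] - tris2[:, 0, 1]) * (tris2[:, 2, 0] - tris2[:, 0, 0]))
    polys = shapely.polygons(tris2[np.abs(cross) > 1e-12])
    merged = shapely.union_all(shapely.make_valid(polys))
    merged = shapely.make_valid(merged)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    # drop interior slivers left by floating-point unions
    return shapely.Polygon(merged.exterior)


def _opening_prism(cavity: SurfaceMesh, face: str, frame_label: str,
                   grow_mm: float = 0.0) -> ExtrudedPolygon:
    axis, sign = face_axis(face, frame_label)
    poly = silhouette_polygon(cavity, axis)
    if grow_mm > 0:
        poly = poly.buffer(grow_mm, quad_segs=16)
    mid = float(cavity.bounds.mean(axis=0)[axis])
    if sign > 0:
        return ExtrudedPolygon(poly, axis, lo=mid, hi=np.inf)
    return ExtrudedPolygon(poly, axis, lo=-np.inf, hi=mid)


def cut_insertion_opening(mould: SurfaceMesh, cavity: SurfaceMesh, face: str,
                          spec: MouldSpec | None = None,
                          pitch_mm: float = DEFAULT_PITCH_MM) -> SurfaceMesh:
    """Open one block face so the specimen can be placed into the cavity.

    Subtracts the prism swept from the cavity silhouette on that face out
    through the block (the swept volume of the specimen sliding in along the
    face normal).
    """
    if spec is not None and face in spec.approaches:
        raise ValueError(
            f"insertion opening cannot be on approach face {face!r}")
    prism = _opening_prism(cavity, face, mould.frame_label)
    field = MeshSDF(mould).difference(prism)
    return extract_surface(field, mould.bounds, pitch_mm,
                           frame_label=mould.frame_label,
                           source_name=f"{mould.source_name}+opening")


# --------------------------------------------------------------------------
# full variant pipeline
# --------------------------------------------------------------------------

@dataclasses.dataclass
class TargetingPlan:
    """Guide plan without carved geometry: everything targeting needs.

    The insertion simulator reads only the spec and the guide table, so a
    plan stands in for a full :class:`MouldModel` when no solid is required
    (the carved variants share this exact plan by construction).
    """

    case_id: str
    block_bounds: np.ndarray
    guides: list[NeedleGuide]
    spec: MouldSpec


def plan_targeting(case: ProstateCase, spec: MouldSpec | None = None
                   ) -> TargetingPlan:
    """Compute the shared guide plan for a case (no surface extraction)."""
    spec = spec or MouldSpec()
    validate(case.boundary)
    block_bounds = np.vstack([case.boundary.bounds[0] - spec.wall_margin_mm,
                              case.boundary.bounds[1] + spec.wall_margin_mm])
    return TargetingPlan(case_id=case.case_id, block_bounds=block_bounds,
                         guides=plan_guides(case, spec, block_bounds),
                         spec=spec)


def plan_guides(case: ProstateCase, spec: MouldSpec,
                block_bounds: np.ndarray) -> list[NeedleGuide]:
    """Centroid -> approaches -> calibrated guides, for every ROI.

    Channels are truncated at the cavity surface, so the collision check uses
    the longest (unoffset) channel extents — axes converging on a shared
    centroid inside the cavity void do not collide.
    """
    guides: list[NeedleGuide] = []
    for label, roi in case.rois.items():
        centroid = center_of_mass(roi)
        for face in choose_approaches(centroid, block_bounds, spec,
                                      frame_label=case.frame_label):
            guides.append(calibrate_guide(centroid, face, block_bounds, spec,
                                          roi_label=label,
                                          frame_label=case.frame_label))
    for g in guides:
        g.channel_length_mm = channel_end_depth(g, case.boundary)
    check_channel_collisions(guides)
    return guides


def _check_opening_clearance(guides, prism, t_ends, spec):
    """A channel crossing the insertion opening loses its wall there; require
    enough remaining guided length (tower + walled channel) to aim a needle."""
    for g, t_end in zip(guides, t_ends):
        n = max(int(t_end / 0.5), 2)
        ts = np.linspace(0.0, t_end, n)
        pts = g.entry_point_mm[None, :] + ts[:, None] * g.direction[None, :]
        walled = prism(pts) > g.channel_diameter_mm / 2.0
        guided = g.tower_height_mm + walled.sum() * (t_end / n)
        if guided < 2.0 * g.channel_diameter_mm:
            raise LayoutError(
                f"guide {g.guide_id!r} is almost entirely inside the "
                f"insertion opening ({guided:.1f} mm of guided length left)")


def build_mould_variants(case: ProstateCase, spec: MouldSpec | None = None
                         ) -> list[MouldModel]:
    """Build one watertight mould solid per cavity offset.

    All variants share the block geometry (sized from the unoffset boundary)
    and the guide plan, so the three printed moulds target identically; only
    the cavity (and hence each channel's terminal depth) changes.
    """
    spec = spec or MouldSpec()
    boundary = case.boundary
    validate(boundary)
    offsets = list(spec.offsets_mm)
    block_lo = boundary.bounds[0] - spec.wall_margin_mm
    block_hi = boundary.bounds[1] + spec.wall_margin_mm
    block_bounds = np.vstack([block_lo, block_hi])
    guides = plan_guides(case, spec, block_bounds)

    boundary_field = MeshSDF(boundary, band=max(offsets) + 4.0)
    axis, _ = face_axis(spec.insertion_face, case.frame_label)
    pitch = spec.grid_pitch_mm

    variants: list[MouldModel] = []
    for delta in offsets:
        cavity_field = boundary_field.offset(delta)
        prism = _opening_prism(boundary, spec.insertion_face,
                               case.frame_label, grow_mm=delta)
        pieces = [Box(block_bounds)]
        cutters = [cavity_field, prism]
        t_ends = []
        bounds = block_bounds.copy()
        for g in guides:
            t_cavity = channel_end_depth(g, boundary, offset_mm=delta)
            t_ends.append(t_cavity)
            r = g.channel_diameter_mm / 2.0
            cutters.append(Cylinder(g.entry_point_mm - g.direction * 2.0,
                                    g.entry_point_mm + g.direction * t_cavity,
                                    r))
            if g.tower_height_mm > 1e-9:
                foot = g.entry_point_mm + g.direction * (g.tower_height_mm + 2.0)
                pieces.append(Cylinder(g.entry_point_mm, foot,
                                       r + spec.tower_wall_mm))
                pad = r + spec.tower_wall_mm
                bounds[0] = np.minimum(bounds[0], g.entry_point_mm - pad)
                bounds[1] = np.maximum(bounds[1], g.entry_point_mm + pad)
        _check_opening_clearance(guides, prism, t_ends, spec)
        solid_field = pieces[0].union(*pieces[1:]) if len(pieces) > 1 else pieces[0]
        solid_field = solid_field.difference(*cutters)
        solid = extract_surface(
            solid_field, bounds, pitch,
            frame_label=case.frame_label,
            source_name=f"{case.case_id}_mould_offset{delta:g}mm")
        cavity_surface = extract_surface(
            cavity_field, boundary.bounds, pitch, level=0.0,
            pad=3.0 + max(offsets),
            frame_label=case.frame_label,
            source_name=f"{case.case_id}_cavity_offset{delta:g}mm")
        vguides = []
        for g, t_end in zip(guides, t_ends):
            gv = copy.deepcopy(g)
            gv.channel_length_mm = float(t_end - 1.0)
            vguides.append(gv)
        variants.append(MouldModel(
            case_id=case.case_id,
            variant_offset_mm=float(delta),
            solid=solid,
            cavity_surface=cavity_surface,
            block_bounds=block_bounds,
            guides=vguides,
            spec=spec,
        ))
    return variants


def verify_mould(model: MouldModel, boundary: SurfaceMesh) -> dict:
    """Post-build checks: watertightness and cavity containment.

    Containment samples the boundary vertices and requires each to be inside
    the cavity surface, with clearance no larger than the variant offset plus
    the extraction pitch.
    """
    checks: dict[str, bool | float] = {}
    checks["solid_watertight"] = model.solid.as_trimesh().is_watertight
    checks["cavity_watertight"] = model.cavity_surface.as_trimesh().is_watertight
    sample = boundary.vertices[:: max(1, len(boundary.vertices) // 300)]
    from .rasterize import surface_distance

    d = surface_distance(sample, model.cavity_surface.vertices,
                         model.cavity_surface.faces)
    inside = raycast.points_inside(sample, model.cavity_surface.vertices,
                                   model.cavity_surface.faces)
    signed = np.where(inside, -d, d)
    # the cavity is a re-sampled surface: allow sub-pitch reconstruction
    # error on "inside", and require clearance <= offset + reconstruction
    tol = 0.5 * model.spec.grid_pitch_mm
    checks["max_signed_distance_mm"] = float(signed.max())
    checks["boundary_inside_cavity"] = bool(signed.max() <= tol)
    checks["max_clearance_mm"] = float(d[inside].max()) if inside.any() else 0.0
    checks["clearance_within_offset"] = bool(
        (-signed).max() <= model.variant_offset_mm
        + 2.0 * model.spec.grid_pitch_mm)
    checks["ok"] = all(v for k, v in checks.items()
                       if isinstance(v, (bool, np.bool_)))
    return checks
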