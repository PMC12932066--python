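"""Needle-guide planning: ROI centres of mass, approach choice, guide-length
calibration and channel carving.

The targeting construction is deliberately simple and exact: every guide
axis is perpendicular to a block face (the inward face normal) and passes
through the ROI's volumetric centre of mass.  The guide *length* is then the
only free parameter, and it is fixed by the calibration identity

    entry -> centroid distance  =  insertion_depth - tip_to_notch_center,

so that a needle inserted to the fixed depth (hub flush with the guide top)
places the centre of its specimen notch exactly on the ROI centroid.  When
the centroid is shallower than that distance, the guide is extended above the
block face by a tower of the required height; when it is deeper, no guide
length can satisfy the identity and calibration fails loudly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import raycast, sdf
from .errors import CalibrationError, LayoutError, MeshValidationError
from .frames import TIE_BREAK_ORDER, face_axis, inward_normal
from .mesh_io import SurfaceMesh, mesh_report


@dataclasses.dataclass
class NeedleGuide:
    """One calibrated guide channel.

    ``entry_point_mm`` is the guide top (where the needle hub stops);
    ``direction`` is the unit inward face normal; ``channel_length_mm`` is
    filled in when the channel is carved (it ends where the cavity begins).
    """

    guide_id: str
    roi_label: str
    approach: str
    entry_point_mm: np.ndarray
    direction: np.ndarray
    tower_height_mm: float
    target_point_mm: np.ndarray
    channel_diameter_mm: float
    channel_length_mm: float | None = None

    @property
    def target_depth_mm(self) -> float:
        """Distance from the guide top to the targeted centroid (the
        calibration identity makes this insertion_depth - tip_to_notch)."""
        return float(np.linalg.norm(self.target_point_mm - self.entry_point_mm))


def center_of_mass(mesh: SurfaceMesh) -> np.ndarray:
    """Volumetric centroid (uniform density) by the divergence theorem."""
    report = mesh_report(mesh)
    if not report.is_watertight:
        raise MeshValidationError(
            f"centre of mass needs a closed surface; defects: {report.defects}",
            report=report)
    tm = mesh.as_trimesh()
    if tm.volume < 0:
        raise MeshValidationError(
            "centre of mass needs outward winding (signed volume > 0)",
            report=report)
    return np.asarray(tm.center_mass, dtype=np.float64)


def _face_coordinate(block_bounds, face: str, frame_label: str) -> tuple[int, int, float]:
    axis, sign = face_axis(face, frame_label)
    coord = block_bounds[1][axis] if sign > 0 else block_bounds[0][axis]
    return axis, sign, float(coord)


def choose_approaches(centroid, block_bounds, spec,
                      frame_label: str = "LPS") -> list[str]:
    """The ``guides_per_roi`` allowed faces nearest the centroid.

    Ranking is by perpendicular centroid-to-face distance; exact ties break
    deterministically in the fixed order superior, posterior, left-lateral,
    right-lateral.
    """
    centroid = np.asarray(centroid, dtype=np.float64)
    block_bounds = np.asarray(block_bounds, dtype=np.float64)
    if not ((block_bounds[0] <= centroid) & (centroid <= block_bounds[1])).all():
        raise ValueError(f"centroid {centroid} lies outside the block")
    allowed = [f for f in spec.approaches if f != spec.insertion_face]
    if spec.guides_per_roi > len(allowed):
        raise ValueError(
            f"guides_per_roi={spec.guides_per_roi} exceeds the "
            f"{len(allowed)} allowed approach faces")
    rank = {f: i for i, f in enumerate(TIE_BREAK_ORDER)}
    scored = []
    for face in allowed:
        axis, _, coord = _face_coordinate(block_bounds, face, frame_label)
        scored.append((abs(centroid[axis] - coord), rank.get(face, len(rank)), face))
    scored.sort()
    return [face for _, _, face in scored[:spec.guides_per_roi]]


def calibrate_guide(centroid, approach: str, block_bounds, spec,
                    roi_label: str = "roi", frame_label: str = "LPS"
                    ) -> NeedleGuide:
    """Construct the guide satisfying the fixed-insertion-depth identity.

    The entry point is placed exactly ``insertion_depth - tip_to_notch_center``
    from the centroid along the outward face normal, so the identity holds by
    construction; ``tower_height`` is what remains above the block face and
    must be >= 0 (a deeper target is unreachable at the fixed depth).
    """
    centroid = np.asarray(centroid, dtype=np.float64)
    block_bounds = np.asarray(block_bounds, dtype=np.float64)
    axis, sign, coord = _face_coordinate(block_bounds, approach, frame_label)
    face_to_centroid = abs(centroid[axis] - coord)
    reach = spec.insertion_depth_mm - spec.needle.tip_to_notch_center_mm
    tower = reach - face_to_centroid
    if tower < 0:
        raise CalibrationError(
            f"target {roi_label!r} lies {face_to_centroid:.1f} mm below the "
            f"{approach} face but the needle reaches only {reach:.1f} mm at "
            f"{spec.insertion_depth_mm:.0f} mm insertion "
            f"(deficit {-tower:.1f} mm)", deficit_mm=float(-tower))
    direction = inward_normal(approach, frame_label)
    entry = centroid.copy()
    entry[axis] = centroid[axis] + sign * reach  # exact identity
    return NeedleGuide(
        guide_id=f"{roi_label}:{approach}",
        roi_label=roi_label,
        approach=approach,
        entry_point_mm=entry,
        direction=direction,
        tower_height_mm=float(tower),
        target_point_mm=centroid,
        channel_diameter_mm=spec.needle.outer_diameter_mm
        + 2.0 * spec.channel_clearance_mm,
    )


def _segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


def check_channel_collisions(guides: list[NeedleGuide], depth_mm: float = 120.0):
    """Raise :class:`LayoutError` naming the first colliding channel pair."""
    segs = [(g.entry_point_mm,
             g.entry_point_mm + g.direction * (g.channel_length_mm or depth_mm))
            for g in guides]
    for i in range(len(guides)):
        for j in range(i + 1, len(guides)):
            dmin = _segment_segment_distance(*segs[i], *segs[j])
            need = (guides[i].channel_diameter_mm
                    + guides[j].channel_diameter_mm) / 2.0
            if dmin < need:
                raise LayoutError(
                    f"guide channels {guides[i].guide_id!r} and "
                    f"{guides[j].guide_id!r} intersect "
                    f"(axis distance {dmin:.2f} mm < {need:.2f} mm)")


def channel_end_depth(guide: NeedleGuide, reference: SurfaceMesh,
                      offset_mm: float = 0.0, overshoot_mm: float = 1.0) -> float:
    """Depth (mm from the guide top) where the channel should stop.

    The channel ends where the cavity begins: at the first crossing of the
    guide axis with the (offset) prostate boundary, plus a small overshoot
    into the void so the carved hole opens cleanly into the cavity.
    """
    crossings = raycast.line_crossings(
        guide.entry_point_mm, guide.direction,
        reference.vertices, reference.faces)
    ahead = crossings[crossings > 0]
    if len(ahead) == 0:
        raise LayoutError(
            f"guide {guide.guide_id!r} axis never reaches the cavity")
    return float(ahead[0]) - offset_mm + overshoot_mm


def carve_guides(mould: SurfaceMesh, guides: list[NeedleGuide],
                 spec, pitch_mm: float | None = None) -> SurfaceMesh:
    """Subtract guide channels from a mould solid and add their towers.

    Channels run from the guide top to the cavity surface (found by probing
    the mould along the axis) and no further; towers are cylinders of wall
    thickness ``spec.tower_wall_mm`` supporting entries above the block face.
    The result is watertight or an error is raised.
    """
    pitch = pitch_mm if pitch_mm is not None else spec.grid_pitch_mm
    check_channel_collisions(guides)
    fields = [sdf.MeshSDF(mould)]
    cut = []
    bounds = mould.bounds.copy()
    for g in guides:
        crossings = raycast.line_crossings(
            g.entry_point_mm, g.direction, mould.vertices, mould.faces)
        ahead = crossings[crossings > 1e-6]
        if len(ahead) < 2:
            raise LayoutError(
                f"guide {g.guide_id!r} does not pass through mould material")
        end = float(ahead[1]) + 1.0  # second crossing = cavity surface
        g.channel_length_mm = float(ahead[1])
        r = g.channel_diameter_mm / 2.0
        cut.append(sdf.Cylinder(g.entry_point_mm - g.direction * 2.0,
                                g.entry_point_mm + g.direction * end, r))
        if g.tower_height_mm > 1e-9:
            foot = g.entry_point_mm + g.direction * (g.tower_height_mm + 2.0)
            fields.append(sdf.Cylinder(g.entry_point_mm, foot,
                                       r + spec.tower_wall_mm))
            bounds[0] = np.minimum(bounds[0], g.entry_point_mm - r - spec.tower_wall_mm)
            bounds[1] = np.maximum(bounds[1], g.entry_point_mm + r + spec.tower_wall_mm)
    solid = fields[0].union(*fields[1:]) if len(fields) > 1 else fields[0]
    solid = solid.difference(*cut)
    return sdf.extract_surface(solid, bounds, pitch,
                               frame_label=mould.frame_label,
                               source_name=f"{mould.source_name}+guides")
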