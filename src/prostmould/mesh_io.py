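"""STL reading, validation, repair and writing.

The currency of the whole pipeline is :class:`SurfaceMesh`: a closed,
consistently wound triangulated surface in millimetres, tagged with the
anatomical frame it lives in.  Loading merges duplicate vertices (STL stores
per-facet vertices) and repairs winding; it never fills holes — a hole in a
boundary segmentation is a data error, not noise, and is reported instead.

STL is unitless; this package fixes millimetres everywhere because that is
what DICOM-derived surface exports use.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError, MeshValidationError

#: Vertices closer than this (mm) are considered identical and merged.
MERGE_TOLERANCE_MM = 1e-6


@dataclasses.dataclass
class SurfaceMesh:
    """Closed triangulated surface in a patient-anatomical frame (mm units).

    Parameters
    ----------
    vertices : (V, 3) float array, millimetres.
    faces : (F, 3) int array of vertex indices, counter-clockwise when seen
        from outside (signed volume > 0).
    frame_label : anatomical frame tag, default ``"LPS"``.
    source_name : free-text provenance label.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame_label: str = "LPS"
    source_name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    # -- conversions ----------------------------------------------------
    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, frame_label: str = "LPS",
                     source_name: str = "") -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces),
                   frame_label=frame_label, source_name=source_name)

    # -- basic measures -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def volume_mm3(self) -> float:
        """Signed volume by the divergence theorem (> 0 when wound outward)."""
        return float(self.as_trimesh().volume)

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min corner, max corner] in mm."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self, **updates) -> "SurfaceMesh":
        kw = dict(vertices=self.vertices.copy(), faces=self.faces.copy(),
                  frame_label=self.frame_label, source_name=self.source_name)
        kw.update(updates)
        return SurfaceMesh(**kw)


@dataclasses.dataclass
class MeshReport:
    """Validation summary of a triangle soup.

    ``signed_volume_mm3`` is the divergence-theorem volume and is negative for
    inward-wound surfaces.  ``defects`` is a list of tags such as
    ``"open_edge"``, ``"non_manifold_edge"``, ``"inverted"``,
    ``"nonfinite_coordinates"``, ``"too_small"``.
    """

    is_watertight: bool
    signed_volume_mm3: float
    n_components: int
    bbox_mm: np.ndarray
    defects: list[str]

    @property
    def signed_volume_ml(self) -> float:
        return self.signed_volume_mm3 / 1000.0


def mesh_report(mesh: SurfaceMesh) -> MeshReport:
    """Inspect a mesh and report defects instead of raising."""
    defects: list[str] = []
    verts, faces = mesh.vertices, mesh.faces
    if not np.isfinite(verts).all():
        defects.append("nonfinite_coordinates")
        finite = verts[np.isfinite(verts).all(axis=1)]
        bbox = (np.vstack([finite.min(axis=0), finite.max(axis=0)])
                if len(finite) else np.zeros((2, 3)))
        return MeshReport(False, float("nan"), 0, bbox, defects)

    tm = mesh.as_trimesh()
    bbox = np.vstack([verts.min(axis=0), verts.max(axis=0)])

    if len(verts) < 4 or len(faces) < 4:
        defects.append("too_small")

    # edge bookkeeping: watertight <=> every undirected edge shared by exactly
    # two faces; winding-consistent <=> each appears once per direction.
    edges = tm.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts == 1).any():
        defects.append("open_edge")
    if (counts > 2).any():
        defects.append("non_manifold_edge")
    watertight = bool(tm.is_watertight)

    volume = float(tm.volume)
    if watertight and volume < 0:
        defects.append("inverted")

    n_components = int(tm.body_count)
    return MeshReport(watertight, volume, n_components, bbox, defects)


def validate(mesh: SurfaceMesh) -> MeshReport:
    """Return a report; raise :class:`MeshValidationError` on any defect."""
    report = mesh_report(mesh)
    bad = [d for d in report.defects if d != "inverted"]
    if bad or not report.is_watertight:
        raise MeshValidationError(
            f"mesh {mesh.source_name!r} fails validation: "
            f"watertight={report.is_watertight}, defects={report.defects}",
            report=report,
        )
    if "inverted" in report.defects:
        raise MeshValidationError(
            f"mesh {mesh.source_name!r} is wound inward (signed volume "
            f"{report.signed_volume_mm3:.3g} mm^3)", report=report)
    return report


def _repair(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices and make the winding consistent/outward.

    These are the only repairs performed automatically; holes are never
    filled.
    """
    tm.merge_vertices(merge_tex=True, merge_norm=True)
    tm.update_faces(tm.nondegenerate_faces())
    tm.update_faces(tm.unique_faces())
    tm.remove_unreferenced_vertices()
    trimesh.repair.fix_winding(tm)
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    return tm


def load_stl(path: str | Path, frame_label: str = "LPS") -> SurfaceMesh:
    """Load a binary or ASCII STL file into a validated :class:`SurfaceMesh`.

    Duplicate vertices are merged (tolerance ~1e-6 mm) and winding is made
    consistent and outward.  Any remaining defect (open edges, non-manifold
    edges) raises :class:`MeshValidationError` carrying a :class:`MeshReport`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise MeshFormatError(f"cannot parse {path} as STL: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    tm = _repair(tm)
    mesh = SurfaceMesh.from_trimesh(tm, frame_label=frame_label,
                                    source_name=path.name)
    validate(mesh)
    return mesh


def save_stl(mesh: SurfaceMesh, path: str | Path,
             dialect: str = "binary") -> Path:
    """Write a validated mesh to STL (``binary`` default, or ``ascii``).

    Refuses non-watertight or non-finite meshes: every emitted STL must be
    printable.  Round-tripping through :func:`load_stl` preserves the vertex
    set to 1e-6 mm and the signed volume to 1e-9 ml.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    validate(mesh)
    path = Path(path)
    tm = mesh.as_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path
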