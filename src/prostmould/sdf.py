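"""Signed-distance-field solid modelling.

Solids are scalar fields negative inside, positive outside.  Boolean
composition uses the standard min/max algebra (union = min, intersection =
max, difference = max(a, -b)); the zero level set of a composed field is the
exact CSG boundary, which is all surface extraction needs.  Fields are
evaluated lazily on a regular grid and the boundary is recovered by marching
cubes, so the result is watertight by construction — the property a
3D-printable mould actually requires — at the cost of re-sampling geometry at
the grid pitch.

Analytic primitives (:class:`Box`, :class:`Cylinder`, :class:`ExtrudedPolygon`)
are exact; a sampled mesh becomes a field through :class:`MeshSDF`
(exact point-to-triangle distance signed by column-crossing parity, see
:mod:`prostmould.rasterize`).  Outward surface offsetting by ``delta`` is the
level shift ``field - delta``.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from . import rasterize, raycast
from .errors import BooleanError
from .mesh_io import SurfaceMesh


class SDF:
    """Scalar field, negative inside the solid."""

    def __call__(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def evaluate_grid(self, origin, pitch: float, shape) -> np.ndarray:
        """Sample the field on a regular grid (override when a grid path is
        cheaper than point evaluation)."""
        pts = rasterize.grid_points(origin, pitch, shape)
        return self(pts).reshape(shape)

    # boolean algebra -----------------------------------------------------
    def union(self, *others: "SDF") -> "SDF":
        return _Combine(np.minimum, (self, *others))

    def intersection(self, *others: "SDF") -> "SDF":
        return _Combine(np.maximum, (self, *others))

    def difference(self, *others: "SDF") -> "SDF":
        return self.intersection(*(_Complement(o) for o in others))

    def offset(self, delta: float) -> "SDF":
        """Outward surface offset by ``delta`` mm (inward if negative)."""
        return _Offset(self, delta)

    __or__ = union
    __and__ = intersection
    __sub__ = difference


class _Combine(SDF):
    def __init__(self, op, children):
        self.op = op
        self.children = tuple(children)

    def __call__(self, points):
        vals = self.children[0](points)
        for child in self.children[1:]:
            vals = self.op(vals, child(points))
        return vals

    def evaluate_grid(self, origin, pitch, shape):
        vals = self.children[0].evaluate_grid(origin, pitch, shape)
        for child in self.children[1:]:
            vals = self.op(vals, child.evaluate_grid(origin, pitch, shape))
        return vals


class _Complement(SDF):
    def __init__(self, child):
        self.child = child

    def __call__(self, points):
        return -self.child(points)

    def evaluate_grid(self, origin, pitch, shape):
        return -self.child.evaluate_grid(origin, pitch, shape)


class _Offset(SDF):
    def __init__(self, child, delta):
        self.child = child
        self.delta = float(delta)

    def __call__(self, points):
        return self.child(points) - self.delta

    def evaluate_grid(self, origin, pitch, shape):
        return self.child.evaluate_grid(origin, pitch, shape) - self.delta


def _box_sdf_grid(bounds, origin, pitch, shape):
    """Exact axis-aligned-box SDF on a grid, built separably (no (N,3)
    point array is ever materialised)."""
    center = bounds.mean(axis=0)
    half = (bounds[1] - bounds[0]) / 2.0
    q = [np.abs(origin[a] + pitch * np.arange(shape[a]) - center[a]) - half[a]
         for a in range(3)]
    qx = q[0][:, None, None]
    qy = q[1][None, :, None]
    qz = q[2][None, None, :]
    outside = np.sqrt(np.maximum(qx, 0.0) ** 2 + np.maximum(qy, 0.0) ** 2
                      + np.maximum(qz, 0.0) ** 2)
    inside = np.minimum(np.maximum(np.maximum(qx, qy), qz), 0.0)
    return outside + inside


def _bounded_grid_eval(field, tight_bounds, pad, origin, pitch, shape):
    """Evaluate ``field`` exactly only inside its padded bounding sub-grid;
    fill the far field with the (positive) distance to that sub-box, which
    preserves all CSG zero crossings."""
    origin = np.asarray(origin, dtype=np.float64)
    lo_idx = np.maximum(np.floor((tight_bounds[0] - pad - origin) / pitch),
                        0).astype(int)
    hi_idx = np.minimum(np.ceil((tight_bounds[1] + pad - origin) / pitch),
                        np.asarray(shape) - 1).astype(int)
    sub_shape = tuple(hi_idx - lo_idx + 1)
    sub_origin = origin + lo_idx * pitch
    sub_pts = rasterize.grid_points(sub_origin, pitch, sub_shape)
    sub = field(sub_pts).reshape(sub_shape)
    if sub_shape == tuple(shape):
        return sub
    grid = np.maximum(_box_sdf_grid(np.asarray(tight_bounds, dtype=float),
                                    origin, pitch, shape), 1e-3)
    grid[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
         lo_idx[2]:hi_idx[2] + 1] = sub
    return grid


class Box(SDF):
    """Axis-aligned box given by its (2, 3) corner bounds. Exact SDF."""

    def __init__(self, bounds):
        self.bounds = np.asarray(bounds, dtype=np.float64)
        self.center = self.bounds.mean(axis=0)
        self.half = (self.bounds[1] - self.bounds[0]) / 2.0

    def __call__(self, points):
        q = np.abs(np.asarray(points, dtype=np.float64) - self.center) - self.half
        outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
        inside = np.minimum(q.max(axis=-1), 0.0)
        return outside + inside

    def evaluate_grid(self, origin, pitch, shape):
        return _box_sdf_grid(self.bounds, origin, pitch, shape)


class Cylinder(SDF):
    """Finite capped cylinder from ``p0`` to ``p1`` with ``radius`` mm."""

    def __init__(self, p0, p1, radius):
        self.p0 = np.asarray(p0, dtype=np.float64)
        self.p1 = np.asarray(p1, dtype=np.float64)
        self.radius = float(radius)
        axis = self.p1 - self.p0
        self.height = float(np.linalg.norm(axis))
        if self.height == 0:
            raise ValueError("degenerate cylinder: p0 == p1")
        self.axis = axis / self.height

    def __call__(self, points):
        rel = np.asarray(points, dtype=np.float64) - self.p0
        along = rel @ self.axis
        radial = np.linalg.norm(rel - np.outer(along, self.axis), axis=-1)
        dx = radial - self.radius
        dy = np.abs(along - self.height / 2.0) - self.height / 2.0
        outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
        inside = np.minimum(np.maximum(dx, dy), 0.0)
        return outside + inside

    def evaluate_grid(self, origin, pitch, shape):
        ends = np.vstack([self.p0, self.p1])
        tight = np.vstack([ends.min(axis=0) - self.radius,
                           ends.max(axis=0) + self.radius])
        return _bounded_grid_eval(self, tight, 2.0, origin, pitch, shape)


class ExtrudedPolygon(SDF):
    """Prism: a 2D polygon extruded along a coordinate axis.

    The polygon lives in the plane of the two non-``axis`` coordinates
    (in natural order); the solid spans ``lo <= x[axis] <= hi`` where either
    end may be infinite.  Used for the specimen-insertion opening, whose
    cross-section is a mesh silhouette (a shapely polygon).
    """

    def __init__(self, polygon, axis: int, lo: float = -np.inf,
                 hi: float = np.inf):
        import shapely

        self.polygon = polygon
        self.axis = int(axis)
        self.lo = float(lo)
        self.hi = float(hi)
        self._shapely = shapely

    def _sdf2d(self, uv: np.ndarray) -> np.ndarray:
        shp = self._shapely
        pts = shp.points(uv)
        d = shp.distance(pts, self.polygon.boundary)
        inside = shp.covers(self.polygon, pts)
        return np.where(inside, -d, d)

    def __call__(self, points):
        points = np.asarray(points, dtype=np.float64)
        other = [a for a in range(3) if a != self.axis]
        f2d = self._sdf2d(points[:, other])
        x = points[:, self.axis]
        ax = np.maximum(self.lo - x, x - self.hi)
        return np.maximum(f2d, ax)

    def evaluate_grid(self, origin, pitch, shape):
        # 2D polygon field computed once per column, broadcast along the axis.
        other = [a for a in range(3) if a != self.axis]
        u = origin[other[0]] + pitch * np.arange(shape[other[0]])
        v = origin[other[1]] + pitch * np.arange(shape[other[1]])
        U, V = np.meshgrid(u, v, indexing="ij")
        f2d = self._sdf2d(np.stack([U.ravel(), V.ravel()], axis=1))
        f2d = f2d.reshape(len(u), len(v))
        x = origin[self.axis] + pitch * np.arange(shape[self.axis])
        ax = np.maximum(self.lo - x, x - self.hi)
        # broadcast the planar field against the axial slab field
        shape3 = [1, 1, 1]
        shape3[self.axis] = shape[self.axis]
        axial = ax.reshape(shape3)
        shape2 = list(shape)
        shape2[self.axis] = 1
        planar = f2d.reshape(shape2)
        return np.maximum(planar, axial)


class MeshSDF(SDF):
    """Signed distance field of a watertight triangle mesh.

    Grid evaluation is exact at each grid node (point-to-triangle distance,
    sign from crossing parity); arbitrary-point evaluation uses ray-parity
    containment and is intended for modest point counts (vertex containment
    checks, probes).
    """

    def __init__(self, mesh: SurfaceMesh, band: float | None = 6.0):
        self.mesh = mesh
        self.band = band
        self._grid_cache: dict[tuple, np.ndarray] = {}

    def __call__(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = rasterize.surface_distance(points, self.mesh.vertices, self.mesh.faces)
        inside = raycast.points_inside(points, self.mesh.vertices, self.mesh.faces)
        return np.where(inside, -d, d)

    def evaluate_grid(self, origin, pitch, shape):
        # mould variants re-sample the same boundary field on the same grid
        # (only the level changes); cache the expensive distance grid.
        key = (bytes(np.asarray(origin, dtype=np.float64)), float(pitch),
               tuple(shape))
        if key not in self._grid_cache:
            if len(self._grid_cache) > 4:
                self._grid_cache.clear()
            self._grid_cache[key] = self._compute_grid(origin, pitch, shape)
        return self._grid_cache[key]

    def _compute_grid(self, origin, pitch, shape):
        # Exact signed distances only on the sub-grid around the mesh; far
        # cells get the (positive) distance to the mesh bounding box, which
        # cannot introduce spurious zero crossings in CSG compositions.
        origin = np.asarray(origin, dtype=np.float64)
        margin = (self.band or 4.0) + 3.0
        mb = self.mesh.bounds
        lo_idx = np.maximum(np.floor((mb[0] - margin - origin) / pitch), 0).astype(int)
        hi_idx = np.minimum(np.ceil((mb[1] + margin - origin) / pitch),
                            np.asarray(shape) - 1).astype(int)
        sub_shape = tuple(hi_idx - lo_idx + 1)
        sub_origin = origin + lo_idx * pitch
        sub = rasterize.signed_distance_grid(
            self.mesh.vertices, self.mesh.faces, sub_origin, pitch, sub_shape,
            band=self.band)
        if sub_shape == tuple(shape):
            return sub
        grid = np.maximum(_box_sdf_grid(mb, origin, pitch, shape), 1e-3)
        grid[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1,
             lo_idx[2]:hi_idx[2] + 1] = sub
        return grid


def extract_surface(field: SDF, bounds, pitch: float, pad: float = 3.0,
                    level: float = 0.0, frame_label: str = "LPS",
                    source_name: str = "csg") -> SurfaceMesh:
    """Extract the ``level`` isosurface of ``field`` as a watertight mesh.

    ``bounds`` must enclose the expected surface; ``pad`` keeps the level set
    away from the grid border (marching cubes cannot close a clipped
    surface).  Raises :class:`BooleanError` if the extracted surface is not
    watertight or is empty.
    """
    origin, shape = rasterize.grid_for_bounds(np.asarray(bounds, dtype=float),
                                              pitch, pad=pad + abs(level))
    grid = field.evaluate_grid(origin, pitch, shape)
    if not (grid.min() < level < grid.max()):
        raise BooleanError(
            f"level {level} isosurface is empty in the sampled region "
            f"(field range {grid.min():.3g}..{grid.max():.3g})")
    verts, faces, _, _ = measure.marching_cubes(
        grid, level=level, spacing=(pitch, pitch, pitch))
    import trimesh

    # marching cubes already emits an indexed, watertight surface; trimesh's
    # vertex merging can fuse near-duplicates into degenerate faces, so the
    # raw topology is kept as-is.
    tm = trimesh.Trimesh(vertices=verts + origin, faces=faces, process=False)
    if tm.volume < 0:
        tm.invert()
    mesh = SurfaceMesh.from_trimesh(tm, frame_label=frame_label,
                                    source_name=source_name)
    tmc = mesh.as_trimesh()
    if not tmc.is_watertight:
        raise BooleanError(
            f"surface extraction produced a non-watertight mesh "
            f"({source_name}); increase resolution (smaller pitch) or check "
            f"that the solids are well separated relative to the pitch")
    return mesh
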