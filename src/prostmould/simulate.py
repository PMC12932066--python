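"""Needle-insertion simulation and targeting verification.

The needle is modelled as its axis plus the specimen-notch interval: inserted
to the fixed depth through a guide, the notch is the segment of length
``notch_length`` centred ``tip_to_notch_center`` behind the tip.  A target is
*hit* when the notch segment intersects the ROI volume; the intersection
length is computed by exact segment/mesh clipping.  Ignoring the finite core
diameter makes the hit criterion conservative (the real needle samples a
cylinder, not a line).

:func:`perturbed_hit_rate` quantifies robustness to placement and
segmentation error: the specimen (boundary + ROIs) is rigidly jittered
relative to the mould — Gaussian translation per axis, Gaussian-angle
rotation about a random axis through the gland centroid, plus a uniform
seating slack when the cavity is offset — and the insertion is re-simulated.
Tissue deformation is deliberately not modelled (rigid-specimen assumption).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import raycast
from .cases import ProstateCase
from .guides import NeedleGuide, center_of_mass
from .mesh_io import SurfaceMesh
from .mould import MouldModel, TargetingPlan
from .needles import NeedleModel
from .phantom import PhantomCase


@dataclasses.dataclass
class ErrorModel:
    """Rigid specimen-placement error: per-axis translation sigma (mm),
    rotation-angle sigma (degrees), and seating slack from boundary offset
    (uniform in a ball of that radius, mm)."""

    translation_sigma_mm: float = 0.0
    rotation_sigma_deg: float = 0.0
    boundary_offset_error_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if (self.translation_sigma_mm < 0 or self.rotation_sigma_deg < 0
                or self.boundary_offset_error_mm < 0):
            raise ValueError("error sigmas must be >= 0")


@dataclasses.dataclass
class TargetingReport:
    """Simulated outcome for one guide.  The deterministic fields describe
    the unperturbed insertion; ``hit_rate`` aggregates perturbed trials and
    is None for a single deterministic simulation."""

    guide_id: str
    axis_to_centroid_mm: float
    notch_roi_intersection_mm: float
    hit: bool
    n_trials: int = 1
    hit_rate: float | None = None


def _notch_segment(guide: NeedleGuide, needle: NeedleModel,
                   insertion_depth_mm: float) -> tuple[np.ndarray, np.ndarray]:
    d = guide.direction
    tip = guide.entry_point_mm + d * insertion_depth_mm
    center = tip - d * needle.tip_to_notch_center_mm
    half = needle.notch_length_mm / 2.0
    return center - d * half, center + d * half


def simulate_insertion(mould: MouldModel | TargetingPlan, guide: NeedleGuide,
                       roi: SurfaceMesh, needle: NeedleModel | None = None
                       ) -> TargetingReport:
    """Advance the needle to the fixed depth along the guide axis and clip
    the notch segment against the ROI surface."""
    needle = needle or mould.spec.needle
    if needle.outer_diameter_mm > guide.channel_diameter_mm:
        raise ValueError(
            f"needle OD {needle.outer_diameter_mm} mm exceeds channel "
            f"diameter {guide.channel_diameter_mm} mm of {guide.guide_id!r}")
    p0, p1 = _notch_segment(guide, needle, mould.spec.insertion_depth_mm)
    length = raycast.segment_inside_length(p0, p1, roi.vertices, roi.faces)
    centroid = center_of_mass(roi)
    rel = centroid - guide.entry_point_mm
    axis_dist = float(np.linalg.norm(rel - (rel @ guide.direction) * guide.direction))
    return TargetingReport(
        guide_id=guide.guide_id,
        axis_to_centroid_mm=axis_dist,
        notch_roi_intersection_mm=float(length),
        hit=length > 0.0,
    )


def _random_rotations(rng, sigma_deg: float, n: int) -> np.ndarray:
    """(n, 3, 3) rotation matrices: Gaussian angle about a uniform axis."""
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.deg2rad(rng.normal(0.0, sigma_deg, size=n)) if sigma_deg > 0 \
        else np.zeros(n)
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axes[:, 2], axes[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axes[:, 2], -axes[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axes[:, 1], axes[:, 0]
    eye = np.eye(3)[None]
    s = np.sin(angles)[:, None, None]
    c = (1 - np.cos(angles))[:, None, None]
    return eye + s * K + c * (K @ K)


def perturbed_hit_rate(mould: MouldModel | TargetingPlan,
                       case: PhantomCase | ProstateCase,
                       err: ErrorModel, n_trials: int
                       ) -> list[TargetingReport]:
    """Monte-Carlo hit rate per guide under rigid specimen jitter.

    The specimen is displaced by the sampled rigid transform; equivalently
    (and cheaply) the notch segment is mapped into the specimen frame by the
    inverse transform and clipped against the unmoved ROI meshes.
    Reproducible for a fixed ``err.seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(err.seed)
    pivot = center_of_mass(case.boundary)
    rotations = _random_rotations(rng, err.rotation_sigma_deg, n_trials)
    translations = (rng.normal(0.0, err.translation_sigma_mm, size=(n_trials, 3))
                    if err.translation_sigma_mm > 0 else np.zeros((n_trials, 3)))
    if err.boundary_offset_error_mm > 0:
        u = rng.normal(size=(n_trials, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = err.boundary_offset_error_mm * rng.uniform(size=n_trials) ** (1 / 3)
        translations = translations + u * radii[:, None]

    spec = mould.spec
    reports = []
    inv_R = np.transpose(rotations, (0, 2, 1))
    for guide in mould.guides:
        roi = case.rois[guide.roi_label]
        p0, p1 = _notch_segment(guide, spec.needle, spec.insertion_depth_mm)
        # specimen frame: x' = R^T (x - pivot - t) + pivot
        a = np.einsum("nij,j->ni", inv_R, p0 - pivot) \
            - np.einsum("nij,nj->ni", inv_R, translations) + pivot
        b = np.einsum("nij,j->ni", inv_R, p1 - pivot) \
            - np.einsum("nij,nj->ni", inv_R, translations) + pivot
        lengths = raycast.segments_inside_length(a, b, roi.vertices, roi.faces)
        base = simulate_insertion(mould, guide, roi)
        reports.append(TargetingReport(
            guide_id=guide.guide_id,
            axis_to_centroid_mm=base.axis_to_centroid_mm,
            notch_roi_intersection_mm=base.notch_roi_intersection_mm,
            hit=base.hit,
            n_trials=n_trials,
            hit_rate=float(np.mean(lengths > 0.0)) if n_trials > 1 else None,
        ))
    return reports


def sphere_notch_hit_probability(radius_mm: float, sigma_mm: float,
                                 notch_length_mm: float,
                                 center_offset_mm: float = 0.0,
                                 n_grid: int = 1501) -> float:
    """Analytic (dense-quadrature) probability that a sphere whose centre is
    displaced by an isotropic 3D Gaussian still intersects a fixed axial
    notch segment.

    The sphere initially sits ``center_offset_mm`` from the notch centre
    along the axis.  By symmetry the displacement reduces to an axial normal
    component and a radial Rayleigh component, leaving a 2D integral of the
    condition ``hypot(rho, max(0, |z| - L/2)) < r`` — independent of the
    Monte-Carlo simulation path, so it can serve as its oracle.
    """
    if sigma_mm <= 0:
        half = notch_length_mm / 2.0
        return float(abs(center_offset_mm) - half < radius_mm)
    half = notch_length_mm / 2.0
    z = np.linspace(-6 * sigma_mm, 6 * sigma_mm, n_grid)
    rho = np.linspace(0.0, 6 * sigma_mm, n_grid)
    fz = np.exp(-z**2 / (2 * sigma_mm**2)) / (np.sqrt(2 * np.pi) * sigma_mm)
    frho = rho / sigma_mm**2 * np.exp(-rho**2 / (2 * sigma_mm**2))
    zc = center_offset_mm + z
    axial = np.maximum(np.abs(zc) - half, 0.0)
    cond = np.hypot(rho[None, :], axial[:, None]) < radius_mm
    inner = np.trapezoid(cond * frho[None, :], rho, axis=1)
    return float(np.trapezoid(inner * fz, z))
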