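"""Conical resection planning and US-overlay projection.

Given the sphere model of the tumor and the scanned liver surface, the
planner inflates the tumor by the chosen safety margin, points the cone's
axis from the tumor centre to the closest point of the liver surface (the
shortest way out), and drops the apex down the axis just far enough that the
cone's lateral surface stays clear of the tumor by the full margin.  For a
cone of half-angle :math:`\\theta` with apex at distance :math:`h` below the
tumor centre along the axis, the distance from the centre to the lateral
surface is :math:`h \\sin\\theta`, so the tangency condition is

.. math:: h = (r_t + m) / \\sin\\theta,

with tumor radius :math:`r_t` and margin :math:`m`.  The resection line —
what the surgeon draws on the liver before cutting — is the closed curve
where the cone's lateral surface crosses the surface mesh.  For navigation,
every planned structure can be intersected with an arbitrary tracked frame's
image plane and drawn in pixel coordinates as an overlay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import trimesh
from scipy.optimize import brentq
from skimage import measure

from .meshdist import closest_point_on_mesh
from .geometry import (
    FramePlane,
    ProbeCalibration,
    TrackedFrame,
    frame_plane,
    world_to_pixel,
)
from .segmentation import TumorModel

__all__ = [
    "PlanConfig",
    "ResectionPlan",
    "OverlayProjection",
    "InfeasiblePlanError",
    "fit_resection_shape",
    "resection_line",
    "project_overlay",
    "cone_implicit",
    "save_plan",
    "load_plan",
]


class InfeasiblePlanError(ValueError):
    """The requested cone cannot achieve the safety margin."""


@dataclass(frozen=True)
class PlanConfig:
    half_angle_deg: float = 45.0
    depth_clearance_mm: float = 2.0   # extra apex depth below the margin sphere
    max_depth_mm: float | None = None  # optional cap on apex depth below the tumor centre
    line_segment_mm: float = 1.0      # target line resolution; bounded below by mesh edge length


@dataclass(frozen=True)
class ResectionPlan:
    """A fitted conical resection: apex, axis (apex -> surface), aperture."""

    apex: np.ndarray
    axis: np.ndarray               # unit vector pointing from apex towards the surface
    half_angle: float              # radians, in (0, pi/2)
    depth_mm: float                # apex depth below the tumor centre along the axis
    safety_margin_mm: float
    resection_line: np.ndarray     # (n, 3) closed polyline on the liver surface

    def __post_init__(self) -> None:
        if not (0.0 < self.half_angle < np.pi / 2):
            raise ValueError("half_angle must lie in (0, pi/2)")
        if self.safety_margin_mm < 0:
            raise ValueError("safety margin must be non-negative")
        a = np.asarray(self.axis, dtype=float).reshape(3)
        object.__setattr__(self, "axis", a / np.linalg.norm(a))
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float).reshape(3))
        object.__setattr__(
            self, "resection_line", np.asarray(self.resection_line, dtype=float).reshape(-1, 3)
        )


def cone_implicit(points: np.ndarray, apex: np.ndarray, axis: np.ndarray, half_angle: float) -> np.ndarray:
    """Signed cone function: negative strictly inside, 0 on the lateral surface.

    For a point with axial height ``z`` above the apex and radial offset
    ``rho``, returns ``rho - z * tan(half_angle)``; points behind the apex
    (z < 0) are always outside.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(apex, dtype=float)
    z = p @ axis
    rho = np.linalg.norm(p - np.outer(z, axis), axis=1)
    f = rho - z * np.tan(half_angle)
    f = np.where(z < 0, np.maximum(f, -z), f)
    return f[0] if np.asarray(points).ndim == 1 else f


def _closest_surface_point(center: np.ndarray, surface: trimesh.Trimesh) -> tuple[np.ndarray, float, int]:
    closest, dist, tri = closest_point_on_mesh(surface, center.reshape(1, 3))
    return closest[0], float(dist[0]), int(tri[0])


def fit_resection_shape(
    tumor: TumorModel,
    surface: trimesh.Trimesh,
    margin_mm: float,
    config: PlanConfig | None = None,
) -> ResectionPlan:
    """Fit the cone around the tumor's safety margin.

    The axis follows the tumor-centre-to-closest-surface-point direction;
    the apex sits on the axis below the tumor at the minimal depth keeping
    the cone's lateral surface at least ``margin_mm`` from the tumor sphere
    (and at least ``depth_clearance_mm`` below the margin sphere).
    """
    config = config or PlanConfig()
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    theta = np.deg2rad(config.half_angle_deg)
    if not (0.0 < theta < np.pi / 2):
        raise InfeasiblePlanError("half angle must lie strictly between 0 and 90 degrees")

    closest, dist, tri = _closest_surface_point(tumor.center, surface)
    if dist <= tumor.radius_mm:
        raise InfeasiblePlanError(
            f"tumor is not strictly below the surface (centre-to-surface distance "
            f"{dist:.2f} mm <= radius {tumor.radius_mm:.2f} mm)"
        )
    # interior test: the outward surface normal at the closest point must
    # point away from the tumor centre
    normal = surface.face_normals[tri]
    if np.dot(closest - tumor.center, normal) < 0:
        raise InfeasiblePlanError("tumor centre lies above/outside the liver surface")

    axis = (closest - tumor.center) / dist
    r_margin = tumor.radius_mm + margin_mm
    depth = max(r_margin / np.sin(theta), r_margin + config.depth_clearance_mm)
    if config.max_depth_mm is not None and depth > config.max_depth_mm:
        min_theta = np.rad2deg(np.arcsin(min(r_margin / config.max_depth_mm, 1.0)))
        raise InfeasiblePlanError(
            f"half angle {config.half_angle_deg:.1f} deg needs apex depth {depth:.1f} mm "
            f"> max {config.max_depth_mm:.1f} mm; minimal feasible half angle is "
            f"{min_theta:.1f} deg"
        )
    apex = tumor.center - axis * depth

    plan = ResectionPlan(
        apex=apex,
        axis=axis,
        half_angle=theta,
        depth_mm=depth,
        safety_margin_mm=margin_mm,
        resection_line=np.zeros((0, 3)),
    )
    line = resection_line(plan, surface, segment_mm=config.line_segment_mm)
    plan = ResectionPlan(
        apex=apex,
        axis=axis,
        half_angle=theta,
        depth_mm=depth,
        safety_margin_mm=margin_mm,
        resection_line=line,
    )

    achieved = depth * np.sin(theta) - tumor.radius_mm
    if achieved < margin_mm - 1e-6:
        raise InfeasiblePlanError(
            f"cone clearance {achieved:.3f} mm below requested margin {margin_mm} mm"
        )
    return plan


def resection_line(
    plan: ResectionPlan, surface: trimesh.Trimesh, segment_mm: float = 1.0
) -> np.ndarray:
    """Closed polyline where the cone's lateral surface crosses the mesh.

    Mesh edges whose endpoints straddle the cone's implicit function are
    root-found (the function is smooth along a straight edge), giving points
    that lie exactly on a mesh edge and on the cone to solver tolerance.
    The crossings are ordered by azimuth about the cone axis.
    """
    f_vertex = cone_implicit(surface.vertices, plan.apex, plan.axis, plan.half_angle)
    edges = surface.edges_unique
    fa, fb = f_vertex[edges[:, 0]], f_vertex[edges[:, 1]]
    crossing = (fa * fb) < 0
    if not np.any(crossing):
        raise InfeasiblePlanError("cone does not intersect the liver surface")

    va = surface.vertices[edges[crossing, 0]]
    vb = surface.vertices[edges[crossing, 1]]
    points = np.empty_like(va)
    for i, (a, b) in enumerate(zip(va, vb)):
        g = lambda t: float(
            cone_implicit(a + t * (b - a), plan.apex, plan.axis, plan.half_angle)
        )
        t = brentq(g, 0.0, 1.0, xtol=1e-12)
        points[i] = a + t * (b - a)

    # order by azimuth about the axis
    e1 = _any_perpendicular(plan.axis)
    e2 = np.cross(plan.axis, e1)
    rel = points - plan.apex
    ang = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(ang)
    line = points[order]
    if line.shape[0] < 3:
        raise InfeasiblePlanError("cone-surface intersection is degenerate")
    return line


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(v, ref)
    return e / np.linalg.norm(e)


@dataclass
class OverlayProjection:
    """Planned structures intersected with one frame, in pixel coordinates.

    ``contours`` maps structure name -> list of (n, 2) pixel arrays
    (columns: x, y); structures absent from the plane yield empty lists with
    their visibility flag preserved, so the display layer can toggle each
    independently.
    """

    contours: dict[str, list[np.ndarray]]
    visible: dict[str, bool]

    STRUCTURES = ("tumor", "safety_margin", "cutting_shape", "cutting_line")

    def toggle(self, structure: str, on: bool) -> None:
        if structure not in self.visible:
            raise KeyError(structure)
        self.visible[structure] = on


def _sphere_plane_circle(
    center: np.ndarray, radius: float, plane: FramePlane, n: int = 128
) -> np.ndarray | None:
    d = float(plane.signed_distance(center))
    if abs(d) >= radius:
        return None
    r = np.sqrt(radius**2 - d**2)
    c = center - d * plane.normal
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return c + r * (np.outer(np.cos(t), plane.axis_x) + np.outer(np.sin(t), plane.axis_y))


def _clip_to_image(px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    inside = (px[:, 0] >= 0) & (px[:, 0] <= w - 1) & (px[:, 1] >= 0) & (px[:, 1] <= h - 1)
    return px[inside]


def project_overlay(
    plan: ResectionPlan,
    tumor: TumorModel,
    frame: TrackedFrame,
    calib: ProbeCalibration,
    grid_step_px: int = 2,
) -> OverlayProjection:
    """Intersect the plan with a frame's image plane and rasterise to pixels.

    Spheres cut the plane in analytic circles; the cone's conic section is
    traced by contouring its implicit function on a pixel grid; resection-
    line vertices within half a pixel spacing of the plane become point
    marks.
    """
    plane = frame_plane(frame, calib)
    h, w = frame.shape
    sx, sy = calib.pixel_spacing

    def to_px(points3d: np.ndarray) -> np.ndarray:
        out = np.empty((points3d.shape[0], 2))
        for i, p in enumerate(points3d):
            u, v, _ = world_to_pixel(frame, calib, p)
            out[i] = (u, v)
        return out

    contours: dict[str, list[np.ndarray]] = {k: [] for k in OverlayProjection.STRUCTURES}

    for name, radius in (("tumor", tumor.radius_mm), ("safety_margin", tumor.radius_mm + plan.safety_margin_mm)):
        circ = _sphere_plane_circle(tumor.center, radius, plane)
        if circ is not None:
            px = _clip_to_image(to_px(circ), frame.shape)
            if px.shape[0]:
                contours[name].append(px)

    # cone section: implicit function sampled on a coarse pixel grid
    us = np.arange(0, w, grid_step_px, dtype=float)
    vs = np.arange(0, h, grid_step_px, dtype=float)
    uu, vv = np.meshgrid(us, vs)
    world = (
        plane.origin
        + (uu * sx)[..., None] * plane.axis_x
        + (vv * sy)[..., None] * plane.axis_y
    )
    fvals = cone_implicit(world.reshape(-1, 3), plan.apex, plan.axis, plan.half_angle)
    fgrid = fvals.reshape(uu.shape)
    if fgrid.min() < 0 < fgrid.max():
        for arc in measure.find_contours(fgrid, 0.0):
            px = np.column_stack([arc[:, 1] * grid_step_px, arc[:, 0] * grid_step_px])
            px = _clip_to_image(px, frame.shape)
            if px.shape[0]:
                contours["cutting_shape"].append(px)

    if plan.resection_line.shape[0]:
        dist = np.abs(plane.signed_distance(plan.resection_line))
        near = plan.resection_line[dist <= max(sx, sy)]
        if near.shape[0]:
            marks = near - np.outer(plane.signed_distance(near), plane.normal)
            px = _clip_to_image(to_px(marks), frame.shape)
            if px.shape[0]:
                contours["cutting_line"].append(px)

    return OverlayProjection(
        contours=contours,
        visible={k: True for k in OverlayProjection.STRUCTURES},
    )


# ---------------------------------------------------------------------------
# Plan serialisation (JSON)

def save_plan(plan: ResectionPlan, path: str | Path) -> None:
    doc = {
        "shape": "cone",
        "apex_mm": plan.apex.tolist(),
        "axis": plan.axis.tolist(),
        "half_angle_deg": float(np.rad2deg(plan.half_angle)),
        "depth_mm": plan.depth_mm,
        "safety_margin_mm": plan.safety_margin_mm,
        "resection_line_mm": plan.resection_line.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_plan(path: str | Path) -> ResectionPlan:
    doc = json.loads(Path(path).read_text())
    return ResectionPlan(
        apex=np.asarray(doc["apex_mm"]),
        axis=np.asarray(doc["axis"]),
        half_angle=float(np.deg2rad(doc["half_angle_deg"])),
        depth_mm=float(doc["depth_mm"]),
        safety_margin_mm=float(doc["safety_margin_mm"]),
        resection_line=np.asarray(doc["resection_line_mm"], dtype=float).reshape(-1, 3),
    )
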