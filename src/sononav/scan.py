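"""Surface scanning: tracked frame stream -> filtered point cloud -> mesh.

The acquisition loop mirrors the navigated-ultrasound scanning procedure:
for every frame, a contact classifier decides whether the transducer face is
on the liver capsule.  Contact frames contribute one candidate surface point
(by default the world-space location of the midpoint of the top image row —
the capsule contact line).  Candidates enter a sliding buffer of the last
``window`` points; once the buffer is deep enough, a candidate is accepted
into the cloud only if its local outlier factor against the buffer stays at
or below a threshold, which rejects tracking glitches.  Losing contact
clears the buffer so that separate sweep segments can never contaminate each
other's density estimates.

The accepted cloud is triangulated into a surface mesh by projecting the
points onto their principal (PCA) plane and Delaunay-triangulating in that
chart — an oriented-points reconstruction suited to the open, height-field-
like patches a liver sweep produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import trimesh
from scipy.spatial import Delaunay

from .contact import CONTACT, ContactModel, predict_contact
from .geometry import ProbeCalibration, TrackedFrame, compose, pixel_to_world
from .lof import local_outlier_factor

__all__ = [
    "ScanConfig",
    "PointCloud3D",
    "ScanError",
    "scan_stream",
    "reconstruct_surface",
    "save_cloud_ply",
    "load_cloud_ply",
]


class ScanError(RuntimeError):
    """Raised when a stream yields no usable surface information."""

    def __init__(self, message: str, partial_cloud: "PointCloud3D | None" = None):
        super().__init__(message)
        self.partial_cloud = partial_cloud


@dataclass(frozen=True)
class PointCloud3D:
    """Accepted surface points (mm) with the frame index each came from."""

    points: np.ndarray                 # (n, 3)
    source_frame_indices: np.ndarray   # (n,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        idx = np.asarray(self.source_frame_indices, dtype=int).reshape(-1)
        if pts.shape[0] != idx.shape[0]:
            raise ValueError("points and source_frame_indices must be parallel")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "source_frame_indices", idx)

    def __len__(self) -> int:
        return self.points.shape[0]


# Acceptance-rule presets.  `standard` follows LOF semantics (inliers score
# ~1, so a tolerance above 1 is needed); the other two reproduce the two
# mutually inconsistent printed variants of the acquisition rule and exist
# for auditability only.
LofRule = Literal["standard", "paper_prose", "paper_pseudocode"]


@dataclass(frozen=True)
class ScanConfig:
    window: int = 10                 # sliding buffer size W ("last 10 points")
    k_neighbors: int = 9             # LOF k; capped at len(buffer) - 1
    lof_threshold: float = 1.5       # accept iff LOF <= threshold (standard rule)
    lof_rule: LofRule = "standard"
    surface_pixel: str = "top_center"   # which pixel becomes the surface point
    min_cloud_size: int = 50         # minimum points before meshing is attempted
    edge_prune_factor: float = 5.0   # drop faces with chart edges > factor x median; 0 disables

    def accept(self, lof: float) -> bool:
        if self.lof_rule == "standard":
            return lof <= self.lof_threshold
        if self.lof_rule == "paper_prose":
            return lof < 1.0
        return lof > 1.0  # paper_pseudocode


def _surface_pixel(frame: TrackedFrame, rule: str) -> tuple[float, float]:
    h, w = frame.shape
    if rule == "top_center":
        return ((w - 1) / 2.0, 0.0)
    if rule == "center":
        return ((w - 1) / 2.0, (h - 1) / 2.0)
    raise ValueError(f"unknown surface pixel rule {rule!r}")


def scan_stream(
    frames: Iterable[TrackedFrame],
    calib: ProbeCalibration,
    model: ContactModel,
    config: ScanConfig | None = None,
    *,
    return_mesh: bool = True,
) -> tuple[PointCloud3D, trimesh.Trimesh | None]:
    """Run the acquisition loop over a tracked stream.

    Returns the filtered cloud and (unless ``return_mesh=False``) the
    reconstructed surface mesh.  Raises :class:`ScanError` if no contact
    frame is seen, or if the cloud is too small to mesh (the partial cloud
    is attached to the exception for inspection).
    """
    config = config or ScanConfig()
    buffer: list[np.ndarray] = []
    accepted: list[np.ndarray] = []
    sources: list[int] = []
    up_sum = np.zeros(3)   # opposite of the image depth axis: points at the probe
    saw_contact = False

    for frame in frames:
        if predict_contact(model, frame.image) != CONTACT:
            buffer.clear()
            continue
        saw_contact = True
        chain = compose(frame.c_t_ms, calib.ms_t_us)
        up_sum -= chain.rotation @ np.array([0.0, 1.0, 0.0])
        p = pixel_to_world(frame, calib, _surface_pixel(frame, config.surface_pixel))
        k = min(config.k_neighbors, len(buffer) - 1)
        if k >= 1 and len(buffer) >= k + 1:
            score = local_outlier_factor(p, np.asarray(buffer), k)
            ok = config.accept(score)
        else:
            ok = True  # buffer still filling: no density estimate yet
        buffer.append(p)
        if len(buffer) > config.window:
            buffer.pop(0)
        if ok:
            accepted.append(p)
            sources.append(frame.index)

    if not saw_contact:
        raise ScanError("no surface acquired: stream contained no contact frames")
    cloud = PointCloud3D(np.asarray(accepted, dtype=float).reshape(-1, 3), np.asarray(sources, dtype=int))
    if not return_mesh:
        return cloud, None
    if len(cloud) < config.min_cloud_size:
        raise ScanError(
            f"cloud of {len(cloud)} points is below the meshing minimum {config.min_cloud_size}",
            partial_cloud=cloud,
        )
    hint = up_sum if np.linalg.norm(up_sum) > 0 else None
    try:
        mesh = reconstruct_surface(cloud, config, outside_direction=hint)
    except ValueError as exc:
        raise ScanError(f"surface reconstruction failed: {exc}", partial_cloud=cloud) from exc
    return cloud, mesh


def reconstruct_surface(
    cloud: PointCloud3D | np.ndarray,
    config: ScanConfig | None = None,
    outside_direction: np.ndarray | None = None,
) -> trimesh.Trimesh:
    """Triangulate a scanned point cloud into an oriented surface mesh.

    Points are projected onto their best-fit (PCA) plane and Delaunay-
    triangulated in that 2D chart; triangle normals are oriented towards
    ``outside_direction`` — the side the probe approached from (+z when not
    given).  Degenerate (sliver) triangles are dropped.
    """
    pts = cloud.points if isinstance(cloud, PointCloud3D) else np.asarray(cloud, dtype=float)
    config = config or ScanConfig()
    if outside_direction is None:
        outside_direction = np.array([0.0, 0.0, 1.0])
    if pts.shape[0] < max(3, 1):
        raise ValueError("reconstruction needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal frame: u, v span the plane, w is the normal direction
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate cloud: points are collinear or coincident")
    uv = centered @ vt[:2].T
    tri = Delaunay(uv)
    faces = tri.simplices.copy()

    # drop slivers (near-zero area in the chart)
    a, b, c = uv[faces[:, 0]], uv[faces[:, 1]], uv[faces[:, 2]]
    area2 = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    faces = faces[area2 > 1e-12]

    # Delaunay fills the convex hull of the chart; faces bridging unsampled
    # regions (sweep turn-arounds, lift-off gaps) show up as overlong edges
    # and are pruned so the mesh only spans what was actually scanned
    if config.edge_prune_factor > 0 and faces.shape[0] > 1:
        a, b, c = uv[faces[:, 0]], uv[faces[:, 1]], uv[faces[:, 2]]
        elen = np.stack([
            np.linalg.norm(b - a, axis=1),
            np.linalg.norm(c - b, axis=1),
            np.linalg.norm(a - c, axis=1),
        ])
        cutoff = config.edge_prune_factor * np.median(elen)
        keep = elen.max(axis=0) <= cutoff
        if keep.any():
            faces = faces[keep]

    mesh = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
    # orient all faces towards the outside (probe) side of the chart
    w = vt[2]
    if np.dot(w, outside_direction) < 0:
        w = -w
    flip = mesh.face_normals @ w < 0
    f = mesh.faces.copy()
    f[flip] = f[flip][:, ::-1]
    return trimesh.Trimesh(vertices=pts, faces=f, process=False)


# ---------------------------------------------------------------------------
# Cloud I/O: ASCII PLY with a per-point source frame index scalar.  Written
# directly because the extra integer vertex property is not representable in
# the mesh library's point-cloud export.

def save_cloud_ply(cloud: PointCloud3D, path: str | Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property double x",
        "property double y",
        "property double z",
        "property int source_frame",
        "end_header",
    ]
    for p, i in zip(cloud.points, cloud.source_frame_indices):
        lines.append(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r} {int(i)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_cloud_ply(path: str | Path) -> PointCloud3D:
    text = Path(path).read_text().splitlines()
    try:
        start = text.index("end_header") + 1
    except ValueError as exc:
        raise ValueError(f"{path}: not an ASCII PLY cloud") from exc
    pts, idx = [], []
    for line in text[start:]:
        if not line.strip():
            continue
        x, y, z, i = line.split()
        pts.append([float(x), float(y), float(z)])
        idx.append(int(i))
    return PointCloud3D(np.asarray(pts), np.asarray(idx))
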