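"""Rigid-transform algebra and the pixel-to-world mapping for tracked ultrasound.

A tracked freehand ultrasound stream consists of 2D B-mode frames, each tagged
with the pose of the probe's optical marker shield in the tracking-camera
frame.  A fixed probe calibration (marker shield -> image plane, plus the
pixel spacing) closes the chain, so that any pixel ``(u, v)`` of frame ``i``
maps to a 3D point in camera coordinates::

    p_world = C_T_MS(i) @ MS_T_US @ T_scale @ (u, v, 0, 1)

Conventions: pixel (0, 0) is the top-left corner of the image, +x runs
rightward (lateral) and +y downward (axial / increasing depth); the image
lives in the z = 0 plane of the US frame.  All 3D quantities are in
millimetres; frames are right-handed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "RigidTransform",
    "ProbeCalibration",
    "TrackedFrame",
    "FramePlane",
    "compose",
    "pixel_to_world",
    "world_to_pixel",
    "frame_plane",
    "load_calibration",
    "save_calibration",
    "load_pose_log",
    "save_pose_log",
]

_RIGID_TOL = 1e-9


class ValidationError(ValueError):
    """An input violates a geometric contract (non-rigid matrix, bad spacing...)."""


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body transform (rotation + translation in mm).

    The rotation block must be orthonormal with determinant +1 to within
    1e-9 and the last row must be (0, 0, 0, 1).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"rigid transform must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("rigid transform contains non-finite entries")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=_RIGID_TOL):
            raise ValidationError("rotation block is not orthonormal (R^T R != I)")
        if not np.isclose(np.linalg.det(r), 1.0, atol=_RIGID_TOL):
            raise ValidationError("rotation block determinant is not +1 (reflection?)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_RIGID_TOL):
            raise ValidationError("last row is not (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Sequence[float]
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one (3,) point or an (n, 3) array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chained transform ``a . b`` (apply ``b`` first, then ``a``)."""
    return RigidTransform(a.matrix @ b.matrix)


@dataclass(frozen=True)
class ProbeCalibration:
    """Fixed probe calibration: marker-shield -> US image frame, plus pixel size.

    ``ms_t_us`` maps US-frame coordinates (mm, image plane at z=0) into the
    marker-shield frame; ``pixel_spacing`` is (mm/px along image x, mm/px
    along image y).  Estimating this calibration (z-wire phantom) is outside
    this package; it is an input.
    """

    ms_t_us: RigidTransform
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        sx, sy = self.pixel_spacing
        if not (sx > 0 and sy > 0):
            raise ValidationError(f"pixel_spacing must be strictly positive, got {self.pixel_spacing}")
        object.__setattr__(self, "pixel_spacing", (float(sx), float(sy)))


@dataclass(frozen=True)
class TrackedFrame:
    """One B-mode image plus the camera -> marker-shield pose it was taken at."""

    image: np.ndarray
    c_t_ms: RigidTransform
    index: int = 0

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2 or img.size == 0:
            raise ValidationError("frame image must be a non-empty 2D array")
        if self.index < 0:
            raise ValidationError("frame index must be non-negative")
        object.__setattr__(self, "image", img)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # (rows, cols) == (height, width)


def _pixel_chain(frame: TrackedFrame, calib: ProbeCalibration) -> RigidTransform:
    """The rigid part of the chain: camera <- marker shield <- US frame."""
    return compose(frame.c_t_ms, calib.ms_t_us)


def pixel_to_world(
    frame: TrackedFrame,
    calib: ProbeCalibration,
    px: Sequence[float],
    *,
    check_bounds: bool = True,
) -> np.ndarray:
    """Map an image pixel ``(u, v)`` to its 3D camera-frame location in mm.

    The pixel is scaled by the pixel spacing into mm in the image plane
    (z = 0 in the US frame), then pushed through the calibration and the
    frame's tracked pose.
    """
    u, v = float(px[0]), float(px[1])
    h, w = frame.shape
    if check_bounds and not (0.0 <= u <= w - 1 and 0.0 <= v <= h - 1):
        raise ValidationError(f"pixel ({u}, {v}) outside image bounds {w}x{h}")
    sx, sy = calib.pixel_spacing
    p_us = np.array([u * sx, v * sy, 0.0])
    return _pixel_chain(frame, calib).apply(p_us)


def world_to_pixel(
    frame: TrackedFrame, calib: ProbeCalibration, point: Sequence[float]
) -> tuple[float, float, float]:
    """Inverse chain: 3D camera-frame point -> (u, v, out-of-plane mm).

    The third value is the signed distance from the image plane in mm
    (0 for points exactly on the plane); callers decide what tolerance
    counts as "in plane".
    """
    p_us = _pixel_chain(frame, calib).inverse().apply(np.asarray(point, dtype=float))
    sx, sy = calib.pixel_spacing
    return p_us[0] / sx, p_us[1] / sy, p_us[2]


@dataclass(frozen=True)
class FramePlane:
    """The world-space plane of one US frame: origin + in-plane axes + normal."""

    origin: np.ndarray      # world position of pixel (0, 0), mm
    axis_x: np.ndarray      # unit vector of increasing image x (lateral)
    axis_y: np.ndarray      # unit vector of increasing image y (depth)
    normal: np.ndarray      # axis_x x axis_y, unit length

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.origin) @ self.normal
        return d[0] if np.asarray(points).ndim == 1 else d


def frame_plane(frame: TrackedFrame, calib: ProbeCalibration) -> FramePlane:
    """World-space image plane of a tracked frame."""
    sx, sy = calib.pixel_spacing
    if sx <= 0 or sy <= 0:
        raise ValidationError("degenerate pixel spacing")
    chain = _pixel_chain(frame, calib)
    origin = chain.apply(np.zeros(3))
    ax = chain.rotation @ np.array([1.0, 0.0, 0.0])
    ay = chain.rotation @ np.array([0.0, 1.0, 0.0])
    normal = np.cross(ax, ay)
    normal /= np.linalg.norm(normal)
    return FramePlane(origin=origin, axis_x=ax, axis_y=ay, normal=normal)


# ---------------------------------------------------------------------------
# External formats: calibration YAML, pose logs (CSV with row-major 3x4, or
# JSON with nested 4x4 arrays).

def save_calibration(calib: ProbeCalibration, path: str | Path) -> None:
    doc = {
        "ms_t_us": [[float(x) for x in row] for row in calib.ms_t_us.matrix],
        "pixel_spacing_mm": [calib.pixel_spacing[0], calib.pixel_spacing[1]],
        "image_convention": "pixel (0,0) top-left; +x lateral right; +y depth down; plane z=0",
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_calibration(path: str | Path) -> ProbeCalibration:
    doc = yaml.safe_load(Path(path).read_text())
    m = np.asarray(doc["ms_t_us"], dtype=float)
    sx, sy = doc["pixel_spacing_mm"]
    return ProbeCalibration(ms_t_us=RigidTransform(m), pixel_spacing=(float(sx), float(sy)))


_POSE_COLS = [f"r{i}{j}" for i in range(3) for j in range(4)]


def save_pose_log(path: str | Path, poses: Iterable[tuple[int, RigidTransform]]) -> None:
    """Write a pose log CSV: columns index, r00..r23 (row-major 3x4)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = [{"index": int(i), "matrix": t.matrix.tolist()} for i, t in poses]
        path.write_text(json.dumps(doc, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index"] + _POSE_COLS)
        for i, t in poses:
            writer.writerow([int(i)] + [repr(float(x)) for x in t.matrix[:3].ravel()])


def load_pose_log(path: str | Path) -> Iterator[tuple[int, RigidTransform]]:
    """Yield (index, pose) pairs from a CSV or JSON pose log, in file order."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        for rec in json.loads(path.read_text()):
            yield int(rec["index"]), RigidTransform(np.asarray(rec["matrix"], dtype=float))
        return
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            m = np.eye(4)
            m[:3] = np.array([float(row[c]) for c in _POSE_COLS]).reshape(3, 4)
            yield int(row["index"]), RigidTransform(m)
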