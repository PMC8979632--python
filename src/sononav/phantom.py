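"""Synthetic phantom: every input the planning pipeline needs, with ground truth.

The generator emulates an ex-vivo liver bench setup: a gently undulating
organ surface (random smooth heightfield), spherical tumor mimics injected
at 10-20 mm depth with diameters drawn from N(12.1, 2.5) mm (truncated above
4 mm), and a tracked ultrasound sweep gliding over the surface.  Contact
frames show multiplicative Rayleigh speckle with hyperechoic (brighter)
lesions and mild depth attenuation, normalised to a fixed mean brightness
the way an auto-gain B-mode device would; no-contact frames show a dark
noise band under the transducer face.  Rendering is appearance-level — the
pipeline consumes intensity statistics and contours, not wave physics.

World frame: z is up, the liver occupies z <= h(x, y).  The probe's image
plane is vertical: image x runs along a horizontal direction, image y
straight down into the tissue, and the midpoint of the top image row is the
transducer-surface contact point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from .contact import CONTACT, NO_CONTACT
from .geometry import ProbeCalibration, RigidTransform, TrackedFrame, compose
from .planning import ResectionPlan
from .segmentation import TumorModel

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "SweepTruth",
    "generate_phantom",
    "simulate_sweep",
    "render_bmode",
    "render_contact_image",
    "render_no_contact_image",
    "simulate_resection",
    "probe_pose",
    "default_calibration",
]


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PhantomConfig:
    """Study-condition knobs for the synthetic bench.

    The tumor diameter and depth distributions default to the ex-vivo
    protocol this bench emulates: diameters N(12.1, 2.5) mm truncated above
    4 mm, centre depths uniform in 10-20 mm below the local surface.
    """

    seed: int = 0

    # surface heightfield
    extent_mm: float = 140.0
    grid_mm: float = 2.0
    surface_amplitude_mm: float = 3.0
    surface_smoothness_mm: float = 20.0

    # tumors
    n_tumors: int = 2
    diameter_mean_mm: float = 12.1
    diameter_sd_mm: float = 2.5
    diameter_min_mm: float = 4.0
    diameter_max_mm: float | None = None   # optional truncation for scenario design
    depth_range_mm: tuple[float, float] = (10.0, 20.0)
    min_clearance_mm: float = 10.0    # surface-to-surface distance between mimics
    placement_border_mm: float = 35.0

    # imaging
    image_width_px: int = 300
    image_height_px: int = 250
    pixel_spacing_mm: tuple[float, float] = (0.2, 0.2)
    background_mean: float = 90.0
    lesion_contrast: float = 2.0
    attenuation_per_mm: float = 0.004
    no_contact_band_mean: float = 8.0
    no_contact_lower_mean: float = 45.0

    # sweep
    n_frames: int = 500
    sweep_span_mm: float = 60.0       # square region scanned, centred on the phantom
    sweep_lines: int = 12             # serpentine line count
    no_contact_fraction: float = 0.1
    no_contact_blocks: int = 2
    pose_noise_mm: float = 0.2
    pose_noise_deg: float = 0.1
    lift_mm: float = 15.0             # probe lift during no-contact stretches

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.image_height_px, self.image_width_px)


def default_calibration(config: PhantomConfig | None = None) -> ProbeCalibration:
    """The bench's fixed probe calibration (a non-trivial rigid offset)."""
    config = config or PhantomConfig()
    rz = _rot_z(np.deg2rad(15.0))
    rx = _rot_x(np.deg2rad(8.0))
    ms_t_us = RigidTransform.from_rotation_translation(rz @ rx, (12.0, -4.0, 6.0))
    return ProbeCalibration(ms_t_us=ms_t_us, pixel_spacing=config.pixel_spacing_mm)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Everything the generator knows: geometry, not estimates."""

    config: PhantomConfig
    surface_mesh: trimesh.Trimesh
    height_fn: Callable[[np.ndarray], np.ndarray]   # (n,2) xy -> z
    tumors: tuple[TumorModel, ...]
    calibration: ProbeCalibration

    def local_depth(self, tumor: TumorModel) -> float:
        """Depth of a tumor centre below the surface point straight above it."""
        z_surf = float(self.height_fn(np.array([tumor.center[:2]]))[0])
        return z_surf - float(tumor.center[2])


@dataclass(frozen=True)
class SweepTruth:
    """Per-frame ground truth recorded during a simulated sweep."""

    contact_labels: tuple[str, ...]
    true_poses: tuple[RigidTransform, ...]          # true camera <- US-frame
    contact_points: np.ndarray                      # (n, 3); NaN rows for no-contact
    lesion_masks: tuple[np.ndarray | None, ...]     # bool masks, None for no-contact


# ---------------------------------------------------------------------------
# Phantom generation


def generate_phantom(config: PhantomConfig | None = None) -> PhantomGroundTruth:
    """Sample a surface heightfield and embedded tumor mimics. Deterministic per seed."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)

    n = int(round(config.extent_mm / config.grid_mm)) + 1
    xs = np.linspace(0.0, config.extent_mm, n)
    noise = rng.standard_normal((n, n))
    sigma = config.surface_smoothness_mm / config.grid_mm
    field = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    field -= field.mean()
    std = field.std()
    if std > 0:
        field *= config.surface_amplitude_mm / std
    # field[i, j] = surface height at (x=xs[i], y=xs[j])
    interp = RegularGridInterpolator((xs, xs), field, bounds_error=False, fill_value=None)

    def height_fn(xy: np.ndarray) -> np.ndarray:
        return np.asarray(interp(np.atleast_2d(xy)), dtype=float)

    surface_mesh = _heightfield_mesh(xs, field)

    tumors: list[TumorModel] = []
    attempts = 0
    lo, hi = config.depth_range_mm
    while len(tumors) < config.n_tumors:
        attempts += 1
        if attempts > 200 * max(config.n_tumors, 1):
            raise RuntimeError(
                f"could not place {config.n_tumors} tumors with clearance "
                f"{config.min_clearance_mm} mm; try fewer tumors or a larger phantom"
            )
        d = float(rng.normal(config.diameter_mean_mm, config.diameter_sd_mm))
        if d <= config.diameter_min_mm:
            continue
        if config.diameter_max_mm is not None and d > config.diameter_max_mm:
            continue
        b = config.placement_border_mm
        x, y = rng.uniform(b, config.extent_mm - b, size=2)
        depth = float(rng.uniform(lo, hi))
        z = float(height_fn(np.array([[x, y]]))[0]) - depth
        cand = TumorModel(center=np.array([x, y, z]), diameter_mm=d)
        ok = all(
            np.linalg.norm(cand.center - t.center) - cand.radius_mm - t.radius_mm
            >= config.min_clearance_mm
            for t in tumors
        )
        if ok:
            tumors.append(cand)

    return PhantomGroundTruth(
        config=config,
        surface_mesh=surface_mesh,
        height_fn=height_fn,
        tumors=tuple(tumors),
        calibration=default_calibration(config),
    )


def _heightfield_mesh(xs: np.ndarray, z: np.ndarray) -> trimesh.Trimesh:
    """Triangulated grid mesh of a heightfield z[i, j] at (xs[i], xs[j])."""
    n = xs.size
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # orient normals up (+z)
    flip = mesh.face_normals[:, 2] < 0
    f = mesh.faces.copy()
    f[flip] = f[flip][:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=f, process=False)


# ---------------------------------------------------------------------------
# B-mode rendering


def render_contact_image(
    shape: tuple[int, int],
    rng: np.random.Generator,
    config: PhantomConfig,
    lesion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Speckled contact frame: Rayleigh texture, hyperechoic lesion, attenuation.

    The mean brightness is renormalised to ``background_mean`` after
    attenuation, emulating a device-side automatic gain.
    """
    h, w = shape
    mean_map = np.full(shape, config.background_mean)
    if lesion_mask is not None:
        mean_map = np.where(lesion_mask, config.background_mean * config.lesion_contrast, mean_map)
    depth_mm = np.arange(h)[:, None] * config.pixel_spacing_mm[1]
    mean_map = mean_map * np.exp(-config.attenuation_per_mm * depth_mm)
    speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
    img = mean_map * speckle
    gain = config.background_mean / img.mean()
    return np.clip(img * gain, 0.0, 255.0)


def render_no_contact_image(
    shape: tuple[int, int], rng: np.random.Generator, config: PhantomConfig
) -> np.ndarray:
    """Frame without capsule contact: dark noisy band under the transducer."""
    h, w = shape
    img = np.empty(shape)
    band = h // 3
    img[:band] = np.abs(rng.normal(config.no_contact_band_mean, 4.0, size=(band, w)))
    lower = config.no_contact_lower_mean * rng.rayleigh(
        scale=np.sqrt(2.0 / np.pi), size=(h - band, w)
    )
    img[band:] = lower
    return np.clip(img, 0.0, 255.0)


def _pixel_world_grid(
    c_t_us: RigidTransform, shape: tuple[int, int], spacing: tuple[float, float]
) -> np.ndarray:
    h, w = shape
    sx, sy = spacing
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.stack([uu * sx, vv * sy, np.zeros_like(uu)], axis=-1)
    return pts @ c_t_us.rotation.T + c_t_us.translation


def lesion_mask_for_pose(
    gt: PhantomGroundTruth, c_t_us: RigidTransform, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Ground-truth lesion mask: pixels whose world position lies inside a tumor."""
    shape = shape or gt.config.image_shape
    world = _pixel_world_grid(c_t_us, shape, gt.config.pixel_spacing_mm)
    mask = np.zeros(shape, dtype=bool)
    for t in gt.tumors:
        mask |= np.linalg.norm(world - t.center, axis=-1) <= t.radius_mm
    return mask


def render_bmode(
    gt: PhantomGroundTruth,
    c_t_us: RigidTransform,
    rng: np.random.Generator,
    contact: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Render one frame at a (true) probe pose; returns (image, lesion mask)."""
    shape = gt.config.image_shape
    if not contact:
        return render_no_contact_image(shape, rng, gt.config), None
    mask = lesion_mask_for_pose(gt, c_t_us, shape)
    return render_contact_image(shape, rng, gt.config, mask), mask


# ---------------------------------------------------------------------------
# Tracked sweep simulation


def _serpentine_path(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, 2) xy positions plus per-frame heading angles."""
    c = config.extent_mm / 2.0
    half = config.sweep_span_mm / 2.0
    ys = np.linspace(c - half, c + half, config.sweep_lines)
    per_line = int(np.ceil(config.n_frames / config.sweep_lines))
    xy = []
    heading = []
    for i, y in enumerate(ys):
        xs = np.linspace(c - half, c + half, per_line)
        if i % 2:
            xs = xs[::-1]
        for x in xs:
            xy.append((x, y))
            heading.append(0.0 if i % 2 == 0 else np.pi)
    xy = np.asarray(xy)[: config.n_frames]
    heading = np.asarray(heading)[: config.n_frames]
    if xy.shape[0] < config.n_frames:
        raise ValueError("sweep path shorter than requested frame count")
    return xy, heading


def probe_pose(
    contact_point: np.ndarray, heading: float, config: PhantomConfig
) -> RigidTransform:
    """True camera <- US-frame pose placing pixel (W/2, 0) at the contact point."""
    ex = np.array([np.cos(heading), np.sin(heading), 0.0])
    ey = np.array([0.0, 0.0, -1.0])                      # image depth axis: straight down
    ez = np.cross(ex, ey)
    r = np.column_stack([ex, ey, ez])
    cx = (config.image_width_px - 1) / 2.0
    origin = contact_point - ex * cx * config.pixel_spacing_mm[0]
    return RigidTransform.from_rotation_translation(r, origin)


def _no_contact_schedule(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean array, True where the probe is lifted; exact requested fraction."""
    n = config.n_frames
    m = int(round(config.no_contact_fraction * n))
    out = np.zeros(n, dtype=bool)
    if m == 0:
        return out
    blocks = max(1, min(config.no_contact_blocks, m))
    sizes = np.full(blocks, m // blocks)
    sizes[: m % blocks] += 1
    # place blocks in distinct, non-adjacent stretches
    starts = np.sort(rng.choice(np.arange(1, n - max(sizes) - 1), size=blocks, replace=False))
    for s, size in zip(starts, sizes):
        out[s : s + size] = True
    # fix the count exactly in case of block overlap
    excess = int(out.sum()) - m
    if excess > 0:
        on = np.flatnonzero(out)
        out[on[:excess]] = False
    elif excess < 0:
        off = np.flatnonzero(~out)
        out[off[:(-excess)]] = True
    return out


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    if sd_deg <= 0:
        return np.eye(3)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def simulate_sweep(
    gt: PhantomGroundTruth, config: PhantomConfig | None = None
) -> tuple[list[TrackedFrame], SweepTruth]:
    """Glide the probe over the surface in a serpentine; emit tracked frames.

    Contact frames put the top-row midpoint on the surface; scheduled
    no-contact frames lift the probe by ``lift_mm``.  Recorded poses carry
    the configured tracking noise; the returned truth holds the noiseless
    poses, contact labels, contact points and lesion masks.
    """
    config = config or gt.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EEB]))
    calib = gt.calibration
    xy, heading = _serpentine_path(config)
    zs = gt.height_fn(xy)
    lifted = _no_contact_schedule(config, rng)

    ms_t_us_inv = calib.ms_t_us.inverse()
    frames: list[TrackedFrame] = []
    labels: list[str] = []
    true_poses: list[RigidTransform] = []
    contact_points = np.full((config.n_frames, 3), np.nan)
    masks: list[np.ndarray | None] = []

    for i in range(config.n_frames):
        contact = not lifted[i]
        point = np.array([xy[i, 0], xy[i, 1], zs[i] + (0.0 if contact else config.lift_mm)])
        c_t_us = probe_pose(point, heading[i], config)
        img, mask = render_bmode(gt, c_t_us, rng, contact=contact)

        noise_t = rng.normal(0.0, config.pose_noise_mm, size=3) if config.pose_noise_mm > 0 else np.zeros(3)
        noise_r = _small_rotation(rng, config.pose_noise_deg)
        noisy = RigidTransform.from_rotation_translation(
            noise_r @ c_t_us.rotation, c_t_us.translation + noise_t
        )
        c_t_ms = compose(noisy, ms_t_us_inv)

        frames.append(TrackedFrame(image=img, c_t_ms=c_t_ms, index=i))
        labels.append(CONTACT if contact else NO_CONTACT)
        true_poses.append(c_t_us)
        if contact:
            contact_points[i] = point
        masks.append(mask)

    truth = SweepTruth(
        contact_labels=tuple(labels),
        true_poses=tuple(true_poses),
        contact_points=contact_points,
        lesion_masks=tuple(masks),
    )
    return frames, truth


# ---------------------------------------------------------------------------
# In-silico resection


def simulate_resection(
    gt: PhantomGroundTruth,
    plan: ResectionPlan,
    execution_noise_mm: float = 0.0,
    tumor: TumorModel | None = None,
    seed: int = 0,
    n_azimuth: int = 96,
    n_axial: int = 40,
) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Cut the planned cone out of the phantom; return (tumor mesh, specimen mesh).

    The specimen is the region enclosed by the cone's lateral surface and the
    liver surface.  Execution noise displaces the lateral cut along its
    outward normal by a smooth random field (Gaussian-filtered white noise on
    the azimuth/height parameterisation, periodic in azimuth, tapered to zero
    at the apex and at the surface rim) — coherent surgical deviation, not
    per-vertex jitter.  Negative field values cut inward; a noisy cut that
    crosses the tumor is returned as-is and will be classified R1 downstream.
    """
    if tumor is None:
        tumor = min(
            gt.tumors,
            key=lambda t: float(np.linalg.norm(np.cross(t.center - plan.apex, plan.axis))),
        )
    tumor_mesh = trimesh.creation.icosphere(subdivisions=3, radius=tumor.radius_mm)
    tumor_mesh.apply_translation(tumor.center)

    a = plan.axis
    e1 = _perp(a)
    e2 = np.cross(a, e1)
    tan_t = np.tan(plan.half_angle)

    # rim: generator heights where each azimuthal cone ray meets the surface
    phis = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    z_top = np.empty(n_azimuth)
    for j, phi in enumerate(phis):
        radial = np.cos(phi) * e1 + np.sin(phi) * e2

        def gap(z: float) -> float:
            p = plan.apex + z * a + z * tan_t * radial
            return float(gt.height_fn(np.array([p[:2]]))[0]) - p[2]

        z_top[j] = brentq(gap, 1e-9, _bracket_surface(gap, plan.depth_mm), xtol=1e-10)

    # smooth execution-noise field on (axial, azimuth), periodic in azimuth
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC07]))
    white = rng.standard_normal((n_axial + 1, n_azimuth))
    smooth = ndimage.gaussian_filter(white, sigma=(3.0, 6.0), mode=("nearest", "wrap"))
    std = smooth.std()
    if std > 0:
        smooth *= execution_noise_mm / std
    s_frac = np.linspace(0.0, 1.0, n_axial + 1)
    taper = np.clip(np.minimum(s_frac, 1.0 - s_frac) * 4.0, 0.0, 1.0)
    smooth *= taper[:, None]

    cos_t, sin_t = np.cos(plan.half_angle), np.sin(plan.half_angle)
    rings = []
    for i, s in enumerate(s_frac[1:], start=1):
        ring = np.empty((n_azimuth, 3))
        for j, phi in enumerate(phis):
            radial = np.cos(phi) * e1 + np.sin(phi) * e2
            z = s * z_top[j]
            base = plan.apex + z * a + z * tan_t * radial
            normal = cos_t * radial - sin_t * a
            disp = smooth[i, j]
            # keep the cut from collapsing through the axis
            disp = max(disp, -(z * tan_t) * 0.9)
            ring[j] = base + disp * normal
        rings.append(ring)

    # top cap: from the rim inward to the surface point above the apex axis
    def surf(xy: np.ndarray) -> np.ndarray:
        z = gt.height_fn(xy)
        return np.column_stack([xy, z])

    rim = rings[-1]
    centre_xy = _axis_surface_point(gt, plan)[:2]
    n_cap = 10
    cap_rings = []
    for q in np.linspace(1.0, 0.0, n_cap + 1)[1:-1]:
        xy = centre_xy * (1 - q) + rim[:, :2] * q
        cap_rings.append(surf(xy))
    centre_vertex = surf(centre_xy.reshape(1, 2))[0]

    verts = [plan.apex.reshape(1, 3)] + rings + cap_rings + [centre_vertex.reshape(1, 3)]
    vertices = np.vstack(verts)
    faces = _lateral_faces(len(rings) + len(cap_rings), n_azimuth)
    specimen = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    trimesh.repair.fix_normals(specimen)
    return tumor_mesh, specimen


def _bracket_surface(gap, scale: float) -> float:
    """Find an upper bound where the ray has crossed above the surface."""
    z_hi = max(scale, 10.0)
    for _ in range(12):
        if gap(z_hi) <= 0:
            return z_hi
        z_hi *= 2.0
    raise ValueError("cone does not reach the surface inside the phantom")


def _axis_surface_point(gt: PhantomGroundTruth, plan: ResectionPlan) -> np.ndarray:
    def gap(z: float) -> float:
        p = plan.apex + z * plan.axis
        return float(gt.height_fn(np.array([p[:2]]))[0]) - p[2]

    z = brentq(gap, 1e-9, _bracket_surface(gap, plan.depth_mm), xtol=1e-10)
    return plan.apex + z * plan.axis


def _lateral_faces(n_rings: int, n_phi: int) -> np.ndarray:
    """Apex fan + quad strips between consecutive rings + centre fan on top."""
    faces = []
    first = 1  # vertex 0 is the apex

    def ring_idx(r: int) -> np.ndarray:
        return first + r * n_phi + np.arange(n_phi)

    r0 = ring_idx(0)
    for j in range(n_phi):
        faces.append([0, r0[j], r0[(j + 1) % n_phi]])
    for r in range(n_rings - 1):
        lo, hi = ring_idx(r), ring_idx(r + 1)
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([lo[j], hi[j], hi[jn]])
            faces.append([lo[j], hi[jn], lo[jn]])
    centre = first + n_rings * n_phi
    top = ring_idx(n_rings - 1)
    for j in range(n_phi):
        faces.append([top[j], centre, top[(j + 1) % n_phi]])
    return np.asarray(faces, dtype=int)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(v, ref)
    return e / np.linalg.norm(e)
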