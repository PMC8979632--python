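import numpy as np
import pytest

from sononav.geometry import ProbeCalibration, RigidTransform, TrackedFrame
from sononav.phantom import (
    PhantomConfig,
    render_contact_image,
    render_no_contact_image,
)
from sononav.scan import (
    PointCloud3D,
    ScanConfig,
    ScanError,
    load_cloud_ply,
    reconstruct_surface,
    save_cloud_ply,
    scan_stream,
)


@pytest.fixture(scope="module")
def frame_bank(phantom_config):
    """A small reusable pool of rendered contact / no-contact images."""
    rng = np.random.default_rng(909)
    shape = (90, 120)
    return (
        [render_contact_image(shape, rng, phantom_config) for _ in range(8)],
        render_no_contact_image(shape, rng, phantom_config),
    )


def make_frame(bank, i, x, y=0.0, z=0.0, contact=True):
    contact_imgs, nc_img = bank
    pose = RigidTransform.from_rotation_translation(np.eye(3), (x, y, z))
    img = contact_imgs[i % len(contact_imgs)] if contact else nc_img
    return TrackedFrame(image=img, c_t_ms=pose, index=i)


@pytest.fixture(scope="module")
def scan_calib():
    return ProbeCalibration(RigidTransform.identity(), (0.2, 0.2))


def serpentine_frames(bank, rng, n_lines=6, per_line=20, jitter=0.0):
    frames = []
    i = 0
    for row in range(n_lines):
        for col in range(per_line):
            x = float(col) + rng.normal(0, jitter)
            y = 3.0 * row + rng.normal(0, jitter)
            frames.append(make_frame(bank, i, x, y, z=rng.normal(0, jitter)))
            i += 1
    return frames


class TestScanStream:
    def test_noiseless_plane_recovered(self, frame_bank, scan_calib, contact_model):
        rng = np.random.default_rng(0)
        frames = serpentine_frames(frame_bank, rng)
        cloud, mesh = scan_stream(frames, scan_calib, contact_model, ScanConfig(min_cloud_size=20))
        # serpentine turn points may read as density changes; the bulk stays
        assert len(cloud) >= 0.9 * len(frames)
        assert np.abs(cloud.points[:, 2]).max() < 1e-9
        assert np.abs(mesh.vertices[:, 2]).max() < 1e-6

    def test_pose_jump_outliers_rejected(self, frame_bank, scan_calib, contact_model):
        rng = np.random.default_rng(1)
        frames = serpentine_frames(frame_bank, rng, jitter=0.05)
        corrupt = {30, 65, 100}
        frames = [
            make_frame(frame_bank, f.index, f.c_t_ms.translation[0], f.c_t_ms.translation[1],
                       z=50.0 if f.index in corrupt else f.c_t_ms.translation[2])
            for f in frames
        ]
        cloud, _ = scan_stream(frames, scan_calib, contact_model,
                               ScanConfig(min_cloud_size=20), return_mesh=False)
        assert not (set(cloud.source_frame_indices.tolist()) & corrupt)
        assert np.abs(cloud.points[:, 2]).max() < 1.0

    def test_no_contact_gap_restarts_buffer(self, frame_bank, scan_calib, contact_model):
        rng = np.random.default_rng(2)
        part1 = [make_frame(frame_bank, i, x=float(i), y=rng.normal(0, 0.05)) for i in range(20)]
        gap = [make_frame(frame_bank, 20 + j, x=0, contact=False) for j in range(5)]
        part2 = [make_frame(frame_bank, 25 + j, x=60.0 + j, y=rng.normal(0, 0.05)) for j in range(20)]
        cloud, _ = scan_stream(part1 + gap + part2, scan_calib, contact_model,
                               ScanConfig(min_cloud_size=10), return_mesh=False)
        xs = cloud.points[:, 0]
        # both sweep segments contribute, nothing bridges the 40 mm gap
        assert np.any(xs < 20 * 0.2 + 20)
        assert np.any(xs > 60)
        assert not np.any((xs > 31.5) & (xs < 59.5))

    def test_no_contact_stream_errors(self, frame_bank, scan_calib, contact_model):
        frames = [make_frame(frame_bank, i, x=float(i), contact=False) for i in range(10)]
        with pytest.raises(ScanError, match="no surface"):
            scan_stream(frames, scan_calib, contact_model)

    def test_small_cloud_error_carries_partial_cloud(self, frame_bank, scan_calib, contact_model):
        frames = [make_frame(frame_bank, i, x=float(i), y=0.1 * (i % 3)) for i in range(10)]
        with pytest.raises(ScanError) as exc:
            scan_stream(frames, scan_calib, contact_model, ScanConfig(min_cloud_size=50))
        assert exc.value.partial_cloud is not None
        assert len(exc.value.partial_cloud) == 10

    def test_deterministic(self, frame_bank, scan_calib, contact_model):
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        f1 = serpentine_frames(frame_bank, rng1, jitter=0.05)
        f2 = serpentine_frames(frame_bank, rng2, jitter=0.05)
        c1, _ = scan_stream(f1, scan_calib, contact_model, return_mesh=False)
        c2, _ = scan_stream(f2, scan_calib, contact_model, return_mesh=False)
        assert np.array_equal(c1.points, c2.points)
        assert np.array_equal(c1.source_frame_indices, c2.source_frame_indices)

    def test_each_point_traces_to_one_contact_frame(self, frame_bank, scan_calib, contact_model):
        rng = np.random.default_rng(4)
        frames = serpentine_frames(frame_bank, rng, jitter=0.02)
        cloud, _ = scan_stream(frames, scan_calib, contact_model, return_mesh=False)
        assert len(np.unique(cloud.source_frame_indices)) == len(cloud)
        assert set(cloud.source_frame_indices) <= {f.index for f in frames}


class TestReconstructSurface:
    def test_plane_patch(self):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(0, 40, 500), rng.uniform(0, 40, 500), np.zeros(500)])
        mesh = reconstruct_surface(PointCloud3D(pts, np.arange(500)))
        assert np.abs(mesh.vertices[:, 2]).max() <= 0.1
        assert mesh.faces.shape[0] > 0

    def test_sphere_cap_hausdorff(self):
        from sononav.meshdist import closest_point_on_mesh

        rng = np.random.default_rng(6)
        R, n = 60.0, 2000
        r = rng.uniform(0, 20.0, n)
        th = rng.uniform(0, 2 * np.pi, n)
        x, y = r * np.cos(th), r * np.sin(th)
        z = np.sqrt(R**2 - x**2 - y**2) - R
        pts = np.column_stack([x, y, z]) + rng.normal(0, 0.2, (n, 3))
        mesh = reconstruct_surface(PointCloud3D(pts, np.arange(n)))
        d_vert = np.abs(np.linalg.norm(mesh.vertices - [0, 0, -R], axis=1) - R)
        m = 1500
        r2, t2 = rng.uniform(0, 19.0, m), rng.uniform(0, 2 * np.pi, m)
        ax, ay = r2 * np.cos(t2), r2 * np.sin(t2)
        az = np.sqrt(R**2 - ax**2 - ay**2) - R
        _, d_true, _ = closest_point_on_mesh(mesh, np.column_stack([ax, ay, az]))
        assert max(d_vert.max(), d_true.max()) <= 1.0

    def test_normals_oriented_consistently(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([rng.uniform(0, 30, 300), rng.uniform(0, 30, 300),
                               rng.normal(0, 0.1, 300)])
        mesh = reconstruct_surface(PointCloud3D(pts, np.arange(300)))
        dots = mesh.face_normals @ np.array([0.0, 0.0, 1.0])
        assert np.all(dots > 0) or np.all(dots < 0)

    def test_degenerate_cloud_rejected(self):
        pts = np.column_stack([np.arange(60.0), np.zeros(60), np.zeros(60)])
        with pytest.raises(ValueError, match="degenerate"):
            reconstruct_surface(PointCloud3D(pts, np.arange(60)))


class TestCloudIO:
    def test_ply_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        cloud = PointCloud3D(rng.normal(0, 10, (25, 3)), np.arange(10, 35))
        path = tmp_path / "cloud.ply"
        save_cloud_ply(cloud, path)
        back = load_cloud_ply(path)
        assert np.array_equal(back.points, cloud.points)
        assert np.array_equal(back.source_frame_indices, cloud.source_frame_indices)
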