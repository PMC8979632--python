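import numpy as np
import pytest
import trimesh

from sononav.geometry import ProbeCalibration, RigidTransform, TrackedFrame, pixel_to_world
from sononav.planning import (
    InfeasiblePlanError,
    PlanConfig,
    cone_implicit,
    fit_resection_shape,
    load_plan,
    project_overlay,
    resection_line,
    save_plan,
)
from sononav.segmentation import TumorModel

from conftest import make_flat_mesh
from oracles import cone_sphere_clearance


@pytest.fixture(scope="module")
def flat():
    return make_flat_mesh()


@pytest.fixture(scope="module")
def tumor():
    return TumorModel(center=np.array([0.0, 0.0, -20.0]), diameter_mm=12.0)


class TestFitResectionShape:
    def test_flat_surface_cone_margin_exact(self, flat, tumor):
        plan = fit_resection_shape(tumor, flat, 10.0, PlanConfig(half_angle_deg=45))
        assert np.allclose(plan.axis, [0, 0, 1], atol=1e-9)
        assert np.allclose(plan.apex[:2], 0, atol=1e-9)
        clearance = cone_sphere_clearance(
            plan.apex, plan.axis, plan.half_angle, tumor.center, tumor.radius_mm
        )
        assert clearance == pytest.approx(10.0, abs=1e-6)

    def test_zero_margin_cone_tangent_to_tumor(self, flat, tumor):
        plan = fit_resection_shape(tumor, flat, 0.0, PlanConfig(half_angle_deg=45))
        clearance = cone_sphere_clearance(
            plan.apex, plan.axis, plan.half_angle, tumor.center, tumor.radius_mm
        )
        assert clearance == pytest.approx(0.0, abs=1e-6)

    def test_tilted_surface_axis_matches_dense_sampling(self, tumor):
        # plane tilted 30 deg about y through the origin
        a = np.deg2rad(30)
        rot = np.array([
            [np.cos(a), 0, np.sin(a)],
            [0, 1, 0],
            [-np.sin(a), 0, np.cos(a)],
        ])
        tilted = make_flat_mesh()
        tilted = trimesh.Trimesh(tilted.vertices @ rot.T, tilted.faces, process=False)
        centre = np.array([0.0, 0.0, -25.0])
        t = TumorModel(center=centre, diameter_mm=12.0)
        plan = fit_resection_shape(t, tilted, 5.0, PlanConfig(half_angle_deg=45))
        # brute-force nearest point by dense sampling of the plane
        uu, vv = np.meshgrid(np.linspace(-60, 60, 1200), np.linspace(-60, 60, 241))
        pts = np.column_stack([uu.ravel(), vv.ravel(), np.zeros(uu.size)]) @ rot.T
        nearest = pts[np.argmin(np.linalg.norm(pts - centre, axis=1))]
        axis_ref = (nearest - centre) / np.linalg.norm(nearest - centre)
        assert np.dot(plan.axis, axis_ref) > 0.9999

    def test_tumor_above_surface_rejected(self, flat):
        t = TumorModel(center=np.array([0.0, 0.0, 20.0]), diameter_mm=12.0)
        with pytest.raises(InfeasiblePlanError):
            fit_resection_shape(t, flat, 10.0)

    def test_infeasible_depth_names_minimal_half_angle(self, flat, tumor):
        cfg = PlanConfig(half_angle_deg=20.0, max_depth_mm=25.0)
        with pytest.raises(InfeasiblePlanError, match="minimal feasible half angle"):
            fit_resection_shape(tumor, flat, 10.0, cfg)

    def test_tumor_sphere_inside_cone(self, flat, tumor):
        plan = fit_resection_shape(tumor, flat, 10.0)
        # sample the tumor sphere surface; all points strictly inside the cone
        rng = np.random.default_rng(1)
        d = rng.standard_normal((500, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        surf = tumor.center + tumor.radius_mm * d
        assert np.all(cone_implicit(surf, plan.apex, plan.axis, plan.half_angle) < 0)

    def test_margin_monotonically_enlarges_resection_line(self, flat, tumor):
        areas = []
        for margin in (2.0, 6.0, 10.0):
            plan = fit_resection_shape(tumor, flat, margin)
            line = plan.resection_line
            # shoelace area of the closed polyline (flat surface: use xy)
            x, y = line[:, 0], line[:, 1]
            areas.append(0.5 * np.abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1))))
        assert areas[0] < areas[1] < areas[2]


class TestResectionLine:
    def test_flat_surface_circle(self, flat):
        plan_no_line = fit_resection_shape(
            TumorModel(center=np.array([0.0, 0.0, -20.0]), diameter_mm=12.0), flat, 10.0,
            PlanConfig(half_angle_deg=45),
        )
        line = plan_no_line.resection_line
        # apex depth h below centre; circle radius = (h + 20) * tan(45)
        want = (plan_no_line.depth_mm + 20.0) * np.tan(plan_no_line.half_angle)
        radii = np.linalg.norm(line[:, :2], axis=1)
        assert np.abs(line[:, 2]).max() <= 0.5
        assert np.abs(radii - want).max() <= 0.5

    def test_vertices_satisfy_both_implicit_equations(self):
        # wavy heightfield
        xs = np.linspace(-60, 60, 121)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        zz = 2.0 * np.sin(xx / 15.0) * np.cos(yy / 18.0)
        verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        idx = np.arange(121 * 121).reshape(121, 121)
        a, b = idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel()
        c, d = idx[1:, :-1].ravel(), idx[1:, 1:].ravel()
        faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
        wavy = trimesh.Trimesh(verts, faces, process=False)
        flip = wavy.face_normals[:, 2] < 0
        f = wavy.faces.copy()
        f[flip] = f[flip][:, ::-1]
        wavy = trimesh.Trimesh(verts, f, process=False)
        t = TumorModel(center=np.array([3.0, -4.0, -22.0]), diameter_mm=10.0)
        plan = fit_resection_shape(t, wavy, 8.0)
        line = plan.resection_line
        f_cone = cone_implicit(line, plan.apex, plan.axis, plan.half_angle)
        assert np.abs(f_cone).max() <= 0.5
        # surface residual: compare against the analytic heightfield
        z_surf = 2.0 * np.sin(line[:, 0] / 15.0) * np.cos(line[:, 1] / 18.0)
        assert np.abs(line[:, 2] - z_surf).max() <= 0.5

    def test_cone_missing_surface_errors(self, flat):
        plan = fit_resection_shape(
            TumorModel(center=np.array([0.0, 0.0, -20.0]), diameter_mm=12.0), flat, 5.0
        )
        deep = type(plan)(
            apex=plan.apex - np.array([0, 0, 2000.0]),
            axis=plan.axis,
            half_angle=np.deg2rad(5.0),
            depth_mm=plan.depth_mm,
            safety_margin_mm=plan.safety_margin_mm,
            resection_line=np.zeros((0, 3)),
        )
        with pytest.raises(InfeasiblePlanError):
            resection_line(deep, flat)


class TestOverlay:
    @pytest.fixture()
    def frame_setup(self):
        calib = ProbeCalibration(RigidTransform.identity(), (0.2, 0.2))
        ex = np.array([1.0, 0, 0])
        ey = np.array([0.0, 0, -1.0])
        r = np.column_stack([ex, ey, np.cross(ex, ey)])

        def make(origin):
            pose = RigidTransform.from_rotation_translation(r, origin)
            return TrackedFrame(image=np.zeros((250, 300)), c_t_ms=pose, index=0), calib

        return make

    def test_equatorial_slice_full_radius(self, flat, tumor, frame_setup):
        plan = fit_resection_shape(tumor, flat, 10.0)
        frame, calib = frame_setup(np.array([-30.0, 0.0, 0.0]))
        ov = project_overlay(plan, tumor, frame, calib)
        pts = np.vstack(ov.contours["tumor"])
        centre = pts.mean(axis=0)
        radii = np.linalg.norm(pts - centre, axis=1)
        assert np.allclose(centre, [30 / 0.2, 20 / 0.2], atol=0.5)
        assert radii.mean() == pytest.approx(tumor.radius_mm / 0.2, abs=0.5)

    def test_offset_slice_reduced_radius(self, flat, tumor, frame_setup):
        plan = fit_resection_shape(tumor, flat, 10.0)
        d = 4.0
        frame, calib = frame_setup(np.array([-30.0, d, 0.0]))
        ov = project_overlay(plan, tumor, frame, calib)
        pts = np.vstack(ov.contours["tumor"])
        radii = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        want = np.sqrt(tumor.radius_mm**2 - d**2) / 0.2
        assert radii.mean() == pytest.approx(want, abs=0.5)

    def test_plane_missing_tumor_empty_contour(self, flat, tumor, frame_setup):
        plan = fit_resection_shape(tumor, flat, 10.0)
        frame, calib = frame_setup(np.array([-30.0, 40.0, 0.0]))
        ov = project_overlay(plan, tumor, frame, calib)
        assert ov.contours["tumor"] == []
        assert ov.visible["tumor"] is True
        # the cone is 40 mm wide at depth: its section can still appear
        assert "cutting_shape" in ov.contours

    def test_structures_toggle_independently(self, flat, tumor, frame_setup):
        plan = fit_resection_shape(tumor, flat, 10.0)
        frame, calib = frame_setup(np.array([-30.0, 0.0, 0.0]))
        ov = project_overlay(plan, tumor, frame, calib)
        ov.toggle("safety_margin", False)
        assert ov.visible["safety_margin"] is False
        assert ov.visible["tumor"] is True
        with pytest.raises(KeyError):
            ov.toggle("nonexistent", False)


class TestPlanIO:
    def test_json_round_trip(self, flat, tumor, tmp_path):
        plan = fit_resection_shape(tumor, flat, 10.0)
        path = tmp_path / "plan.json"
        save_plan(plan, path)
        back = load_plan(path)
        assert np.allclose(back.apex, plan.apex)
        assert np.allclose(back.axis, plan.axis)
        assert back.half_angle == pytest.approx(plan.half_angle)
        assert np.allclose(back.resection_line, plan.resection_line)
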