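import numpy as np
import pytest

from sononav.geometry import ProbeCalibration, RigidTransform, TrackedFrame
from sononav.phantom import PhantomConfig, render_contact_image
from sononav.segmentation import (
    BACKGROUND,
    DEFINITE_FG,
    PROBABLE_FG,
    LabelMask,
    SeedInit,
    SegmentationConfig,
    build_graph_cut,
    graph_cut_segment,
    init_labels,
    mask_to_tumor_model,
    refine_click,
)

from oracles import exhaustive_min_energy, labeling_energy


def lesion_image(rng, shape=(120, 160), centre=(80, 60), radius_px=15, contrast=2.0, bg=90.0):
    """Speckled image with one bright disk; returns (image, truth mask)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= radius_px**2
    mean = np.where(mask, bg * contrast, bg)
    img = mean * rng.rayleigh(scale=np.sqrt(2 / np.pi), size=shape)
    return np.clip(img, 0, 255), mask


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


class TestInitLabels:
    def test_disk_and_annulus_geometry(self, identity_calib):
        seed = SeedInit(center_px=(100, 100), diameter_mm=10, ring_margin_mm=20)
        lm = init_labels((200, 200), seed, identity_calib)
        yy, xx = np.mgrid[0:200, 0:200]
        r = np.hypot(xx - 100, yy - 100)
        assert np.array_equal(lm.labels == DEFINITE_FG, r <= 5)
        assert np.array_equal(lm.labels == PROBABLE_FG, (r > 5) & (r <= 25))

    def test_label_areas_match_analytic_counts(self, identity_calib):
        seed = SeedInit(center_px=(100, 100), diameter_mm=24, ring_margin_mm=30)
        lm = init_labels((220, 220), seed, identity_calib)
        r_fg, r_out = 12.0, 42.0
        area_fg = np.sum(lm.labels == DEFINITE_FG)
        area_ring = np.sum(lm.labels == PROBABLE_FG)
        assert abs(area_fg - np.pi * r_fg**2) <= 2 * np.pi * r_fg
        ring_analytic = np.pi * (r_out**2 - r_fg**2)
        assert abs(area_ring - ring_analytic) <= 2 * np.pi * (r_out + r_fg)

    def test_subpixel_disk_keeps_centre_pixel(self, identity_calib):
        seed = SeedInit(center_px=(50, 50), diameter_mm=0.5)
        lm = init_labels((100, 100), seed, identity_calib)
        assert np.sum(lm.labels == DEFINITE_FG) == 1
        assert lm.labels[50, 50] == DEFINITE_FG

    def test_centre_outside_image_rejected(self, identity_calib):
        with pytest.raises(ValueError, match="outside"):
            init_labels((100, 100), SeedInit(center_px=(150, 50), diameter_mm=10), identity_calib)

    def test_mm_radii_honour_pixel_spacing(self):
        calib = ProbeCalibration(RigidTransform.identity(), (0.5, 0.5))
        seed = SeedInit(center_px=(60, 60), diameter_mm=10, ring_margin_mm=10)
        lm = init_labels((120, 120), seed, calib)
        # 5 mm radius at 0.5 mm/px -> 10 px disk radius
        assert lm.labels[60, 70] == DEFINITE_FG
        assert lm.labels[60, 71] != DEFINITE_FG


class TestGraphCut:
    def test_cut_equals_exhaustive_minimum_on_tiny_instances(self, identity_calib):
        rng = np.random.default_rng(17)
        for trial in range(100):
            h, w = 4, 4
            img = rng.uniform(0, 255, (h, w))
            labels = np.zeros((h, w), dtype=np.uint8)
            labels[1, 1] = DEFINITE_FG
            free = rng.choice(h * w, size=rng.integers(4, 13), replace=False)
            flat = labels.ravel()
            for f in free:
                if flat[f] == BACKGROUND:
                    flat[f] = PROBABLE_FG
            cfg = SegmentationConfig(
                presmooth_sigma=0.0, background_hard=True,
                smoothness=float(rng.uniform(0.5, 8.0)), bins=8,
            )
            problem = build_graph_cut(img, LabelMask(labels), cfg)
            mask = problem.solve()
            e_cut = problem.energy(mask)
            e_min, _ = exhaustive_min_energy(problem)
            assert e_cut == e_min, f"trial {trial}: cut {e_cut} != exhaustive {e_min}"
            # and the implementation's energy agrees with the independent one
            assert e_cut == labeling_energy(problem, mask)

    def test_hard_constraints_respected(self, identity_calib):
        rng = np.random.default_rng(18)
        img, _ = lesion_image(rng)
        seed = SeedInit(center_px=(80, 60), diameter_mm=5.0)
        lm = init_labels(img.shape, seed, identity_calib)
        seg = graph_cut_segment(img, lm, identity_calib)
        assert np.all(seg.mask[lm.labels == DEFINITE_FG])

    def test_energy_not_above_initialization(self, identity_calib):
        rng = np.random.default_rng(19)
        img, _ = lesion_image(rng)
        seed = SeedInit(center_px=(80, 60), diameter_mm=20.0)
        lm = init_labels(img.shape, seed, identity_calib)
        cfg = SegmentationConfig()
        problem = build_graph_cut(img, lm, cfg)
        seg = graph_cut_segment(img, lm, identity_calib, cfg)
        init_energy = problem.energy(lm.labels == DEFINITE_FG)
        assert seg.energy <= init_energy

    def test_uniform_image_collapses_to_definite_fg(self, identity_calib):
        # no contrast at all: the data term is uninformative everywhere and
        # the smoothness term shrinks the mask onto the hard constraint
        img = np.full((100, 100), 120.0)
        seed = SeedInit(center_px=(50, 50), diameter_mm=10.0)
        lm = init_labels(img.shape, seed, identity_calib)
        with pytest.warns(UserWarning, match="overlap"):
            seg = graph_cut_segment(img, lm, identity_calib)
        assert np.array_equal(seg.mask, lm.labels == DEFINITE_FG)

    @pytest.mark.parametrize("contrast", [1.5, 2.0, 3.0])
    def test_dice_on_phantom_lesions(self, identity_calib, contrast):
        rng = np.random.default_rng(int(contrast * 100))
        scores = []
        for _ in range(5):
            img, truth = lesion_image(rng, contrast=contrast)
            seed = SeedInit(center_px=(80, 60), diameter_mm=0.9 * 2 * 15)
            lm = init_labels(img.shape, seed, identity_calib)
            seg = graph_cut_segment(img, lm, identity_calib)
            scores.append(dice(seg.mask, truth))
        assert min(scores) >= 0.90


class TestRefineClick:
    def test_click_inside_removes_region(self, identity_calib):
        rng = np.random.default_rng(21)
        img, _ = lesion_image(rng)
        seed = SeedInit(center_px=(80, 60), diameter_mm=27.0)
        lm = init_labels(img.shape, seed, identity_calib)
        seg = graph_cut_segment(img, lm, identity_calib)
        click = (80, 60)
        assert seg.mask[click[1], click[0]]
        refined, _ = refine_click(img, seg, lm, click, identity_calib)
        assert not refined.mask[click[1], click[0]]

    def test_click_on_missed_lobe_improves_dice(self, identity_calib):
        rng = np.random.default_rng(22)
        shape = (120, 160)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        lobe_a = (xx - 70) ** 2 + (yy - 60) ** 2 <= 14**2
        lobe_b = (xx - 100) ** 2 + (yy - 60) ** 2 <= 9**2
        truth = lobe_a | lobe_b
        img = np.clip(np.where(truth, 180, 90) * rng.rayleigh(np.sqrt(2 / np.pi), shape), 0, 255)
        seed = SeedInit(center_px=(70, 60), diameter_mm=25.0, ring_margin_mm=15.0)
        lm = init_labels(shape, seed, identity_calib)
        cfg = SegmentationConfig(background_hard=True)
        seg = graph_cut_segment(img, lm, identity_calib, cfg)
        d0 = dice(seg.mask, truth)
        if not seg.mask[60, 100]:
            refined, _ = refine_click(img, seg, lm, (100, 60), identity_calib, cfg)
            assert dice(refined.mask, truth) > d0

    def test_double_click_is_approximate_involution(self, identity_calib):
        rng = np.random.default_rng(23)
        img, _ = lesion_image(rng)
        seed = SeedInit(center_px=(80, 60), diameter_mm=27.0)
        lm = init_labels(img.shape, seed, identity_calib)
        seg = graph_cut_segment(img, lm, identity_calib)
        click = (85, 64)
        once, lm1 = refine_click(img, seg, lm, click, identity_calib)
        twice, _ = refine_click(img, once, lm1, click, identity_calib)
        assert dice(twice.mask, seg.mask) >= 0.98


class TestTumorModel:
    def test_disk_to_sphere_identity_pose(self, identity_calib):
        rng = np.random.default_rng(24)
        img, _ = lesion_image(rng, centre=(100, 100), radius_px=5)
        yy, xx = np.mgrid[0:120, 0:160]
        mask = (xx - 100) ** 2 + (yy - 100) ** 2 <= 5**2
        from sononav.segmentation import SegmentationResult

        seg = SegmentationResult(mask=mask, center_px=(100.0, 100.0),
                                 equiv_diameter_mm=2 * np.sqrt(mask.sum() / np.pi), energy=0.0)
        frame = TrackedFrame(image=img, c_t_ms=RigidTransform.identity(), index=0)
        tm = mask_to_tumor_model(seg, frame, identity_calib)
        assert np.allclose(tm.center, [100, 100, 0])
        assert tm.diameter_mm == pytest.approx(10.0, abs=0.5)

    def test_translation_carries_centre(self, identity_calib):
        mask = np.zeros((120, 160), dtype=bool)
        yy, xx = np.mgrid[0:120, 0:160]
        mask[(xx - 100) ** 2 + (yy - 100) ** 2 <= 25] = True
        from sononav.segmentation import SegmentationResult

        seg = SegmentationResult(mask=mask, center_px=(100.0, 100.0),
                                 equiv_diameter_mm=10.0, energy=0.0)
        pose = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, 30))
        frame = TrackedFrame(image=np.zeros((120, 160)), c_t_ms=pose, index=0)
        tm = mask_to_tumor_model(seg, frame, identity_calib)
        assert np.allclose(tm.center, [100, 100, 30])

    def test_elliptical_mask_equiv_diameter(self, identity_calib):
        yy, xx = np.mgrid[0:200, 0:200]
        mask = ((xx - 100) / 20.0) ** 2 + ((yy - 100) / 10.0) ** 2 <= 1.0
        area = mask.sum()
        from sononav.segmentation import SegmentationResult

        seg = SegmentationResult(mask=mask, center_px=(100.0, 100.0),
                                 equiv_diameter_mm=2 * np.sqrt(area / np.pi), energy=0.0)
        frame = TrackedFrame(image=np.zeros((200, 200)), c_t_ms=RigidTransform.identity(), index=0)
        tm = mask_to_tumor_model(seg, frame, identity_calib)
        assert tm.diameter_mm == pytest.approx(2 * np.sqrt(area / np.pi))
        # and that count approximates the analytic ellipse area pi*a*b
        assert area == pytest.approx(np.pi * 20 * 10, rel=0.02)
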