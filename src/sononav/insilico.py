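"""In-silico resection experiments: the full pipeline against ground truth.

This module plays the role of the bench evaluation: for each seed it builds
a phantom, scans it with the tracked probe, segments the tumor on a frozen
midsection frame (a simulated operator places the probe over the lesion and
clicks near its centre), fits the 10 mm-margin cone on the *scanned* surface,
executes the cut in silico and measures the achieved margin against the
*true* tumor.  Because every stage runs on estimated quantities while the
margin is scored against ground truth, the recovered margin reflects the
accumulated error of the whole method, not of any single stage.

Scenario design: tumors sit at 18-20 mm depth with diameters capped at
13 mm so that the cut (cone) surface — not the intact liver above the
tumor — is the closest specimen boundary.  Shallower tumors would make the
minimum distance measure overlying parenchyma the knife never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import (
    CONTACT,
    NO_CONTACT,
    ContactModel,
    extract_features,
    train_contact_model,
)
from .margins import MarginReport, measure_margin
from .phantom import (
    PhantomConfig,
    PhantomGroundTruth,
    probe_pose,
    generate_phantom,
    render_bmode,
    render_contact_image,
    render_no_contact_image,
    simulate_resection,
    simulate_sweep,
)
from .planning import PlanConfig, ResectionPlan, fit_resection_shape
from .scan import ScanConfig, scan_stream
from .segmentation import (
    SeedInit,
    SegmentationConfig,
    TumorModel,
    graph_cut_segment,
    init_labels,
    mask_to_tumor_model,
)
from .geometry import RigidTransform, TrackedFrame, compose

__all__ = [
    "ExperimentConfig",
    "VirtualResectionResult",
    "default_experiment_phantom",
    "train_default_contact_model",
    "run_virtual_resection",
]


@dataclass(frozen=True)
class ExperimentConfig:
    margin_mm: float = 10.0
    execution_noise_mm: float = 0.0
    click_jitter_px: float = 2.0
    diameter_guess_rel_error: float = 0.10  # operator's size guess: +-10%
    scan: ScanConfig = field(default_factory=ScanConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)


def default_experiment_phantom(seed: int) -> PhantomConfig:
    """Phantom conditions for margin-recovery experiments (see module docs)."""
    return PhantomConfig(
        seed=seed,
        n_tumors=1,
        depth_range_mm=(18.0, 20.0),
        diameter_max_mm=13.0,
        extent_mm=140.0,
        placement_border_mm=65.0,   # tumor within ~5 mm of the phantom centre
        sweep_span_mm=112.0,        # scan covers the whole resection-line circle
        sweep_lines=23,
        n_frames=230,
        image_width_px=200,
        image_height_px=200,
    )


def train_default_contact_model(seed: int = 0, n_per_class: int = 80) -> ContactModel:
    """Train the contact SVM on freshly rendered phantom frames."""
    cfg = PhantomConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AC7]))
    shape = (120, 160)
    feats, labels = [], []
    for _ in range(n_per_class):
        feats.append(extract_features(render_contact_image(shape, rng, cfg)))
        labels.append(CONTACT)
        feats.append(extract_features(render_no_contact_image(shape, rng, cfg)))
        labels.append(NO_CONTACT)
    return train_contact_model(feats, labels)


@dataclass(frozen=True)
class VirtualResectionResult:
    seed: int
    true_tumor: TumorModel
    estimated_tumor: TumorModel
    plan: ResectionPlan
    report: MarginReport
    ground_truth: PhantomGroundTruth

    @property
    def min_margin_mm(self) -> float:
        return self.report.min_margin_mm

    @property
    def r_status(self) -> str:
        return self.report.r_status


def _frozen_midsection_frame(
    gt: PhantomGroundTruth, rng: np.random.Generator, config: PhantomConfig
) -> tuple[TrackedFrame, RigidTransform]:
    """The operator centres the probe over the lesion and freezes the image."""
    tumor = gt.tumors[0]
    surf_z = float(gt.height_fn(tumor.center[:2][None])[0])
    contact_point = np.array([tumor.center[0], tumor.center[1], surf_z])
    c_t_us = probe_pose(contact_point, 0.0, config)
    img, _ = render_bmode(gt, c_t_us, rng, contact=True)
    # the recorded pose carries tracking noise, like any sweep frame
    noise_t = rng.normal(0.0, config.pose_noise_mm, 3)
    noisy = RigidTransform.from_rotation_translation(
        c_t_us.rotation, c_t_us.translation + noise_t
    )
    c_t_ms = compose(noisy, gt.calibration.ms_t_us.inverse())
    return TrackedFrame(image=img, c_t_ms=c_t_ms, index=10_000), c_t_us


def run_virtual_resection(
    seed: int,
    contact_model: ContactModel,
    config: ExperimentConfig | None = None,
    phantom: PhantomConfig | None = None,
) -> VirtualResectionResult:
    """One complete planned resection on a fresh phantom; margin vs ground truth."""
    config = config or ExperimentConfig()
    pcfg = phantom or default_experiment_phantom(seed)
    gt = generate_phantom(pcfg)
    true_tumor = gt.tumors[0]

    frames, _ = simulate_sweep(gt, pcfg)
    _, surface = scan_stream(frames, gt.calibration, contact_model, config.scan)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF20]))
    frozen, c_t_us = _frozen_midsection_frame(gt, rng, pcfg)
    p_us = c_t_us.inverse().apply(true_tumor.center)
    sx, sy = pcfg.pixel_spacing_mm
    click = (
        p_us[0] / sx + rng.uniform(-config.click_jitter_px, config.click_jitter_px),
        p_us[1] / sy + rng.uniform(-config.click_jitter_px, config.click_jitter_px),
    )
    guess = true_tumor.diameter_mm * (
        1.0 + rng.uniform(-config.diameter_guess_rel_error, config.diameter_guess_rel_error)
    )
    seed_init = SeedInit(center_px=click, diameter_mm=guess)
    labels = init_labels(frozen.shape, seed_init, gt.calibration)
    seg = graph_cut_segment(frozen.image, labels, gt.calibration, config.segmentation)
    est_tumor = mask_to_tumor_model(seg, frozen, gt.calibration)

    plan = fit_resection_shape(est_tumor, surface, config.margin_mm, config.plan)
    tumor_mesh, specimen = simulate_resection(
        gt, plan, config.execution_noise_mm, tumor=true_tumor, seed=seed
    )
    report = measure_margin(tumor_mesh, specimen)
    return VirtualResectionResult(
        seed=seed,
        true_tumor=true_tumor,
        estimated_tumor=est_tumor,
        plan=plan,
        report=report,
        ground_truth=gt,
    )
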