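"""End-to-end planning pipeline with file I/O, manifests and provenance.

Ties the stages into the operator workflow: scan the liver surface from a
tracked frame stream, segment the tumor on a chosen frozen frame from a seed
click, lift the mask to a sphere model, fit the conical resection plan, and
project the overlay onto the frozen frame.  All interactivity (the frozen
frame choice, the seed click, refinement clicks) is replayed from config, so
a run is fully determined by its inputs — the manifest records config,
input checksums, stage timings and output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import __version__
from .contact import ContactModel, load_contact_model
from .geometry import (
    ProbeCalibration,
    TrackedFrame,
    load_calibration,
    load_pose_log,
    save_pose_log,
)
from .planning import PlanConfig, fit_resection_shape, project_overlay, save_plan
from .scan import PointCloud3D, ScanConfig, save_cloud_ply, scan_stream
from .segmentation import (
    SeedInit,
    SegmentationConfig,
    graph_cut_segment,
    init_labels,
    mask_to_tumor_model,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_planning_pipeline",
    "load_frames",
    "save_frames",
]


@dataclass(frozen=True)
class PipelineConfig:
    frames_dir: str
    poses_csv: str
    calibration_yaml: str
    contact_model: str
    # segmentation seed (replayed operator input)
    seed_frame_index: int = 0
    seed_center_px: tuple[float, float] = (0.0, 0.0)
    seed_diameter_mm: float = 12.0
    ring_margin_mm: float = 20.0
    # stage configs
    scan: ScanConfig = field(default_factory=ScanConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    margin_mm: float = 10.0
    r0_threshold_mm: float = 1.0
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    outputs: dict[str, str]
    timings_s: dict[str, float]
    version: str
    timestamp: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_inputs(config: PipelineConfig) -> dict[str, str]:
    sums: dict[str, str] = {}
    for name in ("poses_csv", "calibration_yaml", "contact_model"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name}: {p} does not exist")
        sums[name] = _sha256(p)
    frames = sorted(Path(config.frames_dir).glob("frame_*.png"))
    if not frames:
        raise FileNotFoundError(f"frames_dir: no frame_*.png in {config.frames_dir}")
    h = hashlib.sha256()
    for f in frames:
        h.update(f.read_bytes())
    sums["frames"] = h.hexdigest()
    return sums


def save_frames(frames: list[TrackedFrame], out_dir: str | Path) -> None:
    """Write a tracked stream as frame_NNNNN.png images plus a pose CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in frames:
        img = Image.fromarray(np.clip(f.image, 0, 255).astype(np.uint8))
        img.save(out / f"frame_{f.index:05d}.png")
    save_pose_log(out / "poses.csv", [(f.index, f.c_t_ms) for f in frames])


def load_frames(frames_dir: str | Path, poses_csv: str | Path) -> list[TrackedFrame]:
    poses = dict(load_pose_log(poses_csv))
    frames = []
    for p in sorted(Path(frames_dir).glob("frame_*.png")):
        idx = int(p.stem.split("_")[1])
        if idx not in poses:
            raise ValueError(f"frame {idx} has no pose in {poses_csv}")
        img = np.asarray(Image.open(p), dtype=float)
        frames.append(TrackedFrame(image=img, c_t_ms=poses[idx], index=idx))
    if not frames:
        raise FileNotFoundError(f"no frame_*.png found in {frames_dir}")
    return frames


def run_planning_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Scan -> segment -> model -> plan -> overlay; write outputs + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = _checksum_inputs(config)  # fails fast before writing anything

    calib = load_calibration(config.calibration_yaml)
    model = load_contact_model(config.contact_model)
    frames = load_frames(config.frames_dir, config.poses_csv)

    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("scan"):
        cloud, surface = scan_stream(frames, calib, model, config.scan)
        save_cloud_ply(cloud, out / "cloud.ply")
        surface.export(out / "surface.ply")
        outputs["cloud"] = str(out / "cloud.ply")
        outputs["surface"] = str(out / "surface.ply")

    with stage("segment"):
        by_index = {f.index: f for f in frames}
        frozen = by_index[config.seed_frame_index]
        seed = SeedInit(
            center_px=config.seed_center_px,
            diameter_mm=config.seed_diameter_mm,
            ring_margin_mm=config.ring_margin_mm,
        )
        labels = init_labels(frozen.shape, seed, calib)
        seg = graph_cut_segment(frozen.image, labels, calib, config.segmentation)
        mask_img = Image.fromarray((seg.mask * 255).astype(np.uint8))
        mask_img.save(out / "tumor_mask.png")
        outputs["tumor_mask"] = str(out / "tumor_mask.png")

    with stage("model"):
        tumor = mask_to_tumor_model(seg, frozen, calib)
        (out / "tumor.json").write_text(
            json.dumps(
                {"center_mm": tumor.center.tolist(), "diameter_mm": tumor.diameter_mm},
                indent=1,
            )
        )
        outputs["tumor"] = str(out / "tumor.json")

    with stage("plan"):
        plan = fit_resection_shape(tumor, surface, config.margin_mm, config.plan)
        save_plan(plan, out / "plan.json")
        outputs["plan"] = str(out / "plan.json")

    with stage("overlay"):
        overlay = project_overlay(plan, tumor, frozen, calib)
        doc = {
            name: [c.tolist() for c in contours]
            for name, contours in overlay.contours.items()
        }
        (out / "overlay.json").write_text(json.dumps(doc, indent=1))
        outputs["overlay"] = str(out / "overlay.json")

    manifest = RunManifest(
        config=_config_dict(config),
        input_checksums=checksums,
        outputs=outputs,
        timings_s=timings,
        version=__version__,
        timestamp=time.time(),
    )
    tmp = out / "manifest.json.tmp"
    tmp.write_text(manifest.to_json())
    tmp.replace(out / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d))  # normalise tuples -> lists
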