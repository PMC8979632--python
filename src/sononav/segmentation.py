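"""Seeded graph-cut tumor segmentation on a frozen B-mode frame.

The operator clicks the tumor centre on the frame showing the lesion's
largest diameter and supplies an approximate diameter.  A disk of that
diameter is labelled *definitely foreground*, the surrounding annulus out to
a configurable ring margin (20 mm by default) *probably foreground*, and
everything outside *background*.  Intensity histograms fitted to the
definite-foreground disk and to the background region give per-pixel data
terms; a contrast-weighted Potts term on the pixel grid enforces coherent
boundaries; the optimal binary labelling is the minimum s-t cut of the
corresponding flow network.  Mis-segmented areas are fixed by single clicks:
clicking inside the current mask carves the local area out, clicking outside
adds it, and the cut is re-run.

Capacities are quantized to integers (scale 1e4) for the max-flow solver;
:class:`GraphCutProblem` exposes the exact quantized energy so the returned
labelling can be checked against exhaustive enumeration on tiny instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .geometry import ProbeCalibration, TrackedFrame, pixel_to_world

__all__ = [
    "SeedInit",
    "LabelMask",
    "SegmentationConfig",
    "SegmentationResult",
    "GraphCutProblem",
    "TumorModel",
    "init_labels",
    "graph_cut_segment",
    "refine_click",
    "mask_to_tumor_model",
]

# label codes
BACKGROUND = 0
PROBABLE_FG = 1
DEFINITE_FG = 2

_CAP_SCALE = 10_000  # integer quantization of unit energy for the flow solver


@dataclass(frozen=True)
class SeedInit:
    """Operator initialisation: a centre click plus an approximate diameter."""

    center_px: tuple[float, float]
    diameter_mm: float
    ring_margin_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.ring_margin_mm <= 0:
            raise ValueError("ring_margin_mm must be positive")


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel trimap: definite foreground / probable foreground / background."""

    labels: np.ndarray  # uint8 array of {BACKGROUND, PROBABLE_FG, DEFINITE_FG}

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.any(lab == DEFINITE_FG):
            raise ValueError("label mask must contain a non-empty definite-foreground region")
        object.__setattr__(self, "labels", lab.astype(np.uint8))


@dataclass(frozen=True)
class SegmentationConfig:
    smoothness: float = 6.0        # lambda: weight of the boundary term
    bins: int = 32                 # intensity histogram bins
    connectivity: int = 4          # 4- or 8-connected pixel grid
    presmooth_sigma: float = 1.5   # Gaussian presmoothing (px) for the data term; 0 disables
    background_hard: bool = False  # hard-constrain pixels outside the ring?
    background_soft_penalty: float = 1.5  # -log-units added to fg cost of soft background seeds
    overlap_warn_limit: float = 0.85      # histogram overlap above which a warning is raised
    refine_radius_mm: float = 3.0  # neighbourhood re-seeded by a correction click


@dataclass(frozen=True)
class SegmentationResult:
    """Binary tumor mask with its centroid and equivalent-circle diameter."""

    mask: np.ndarray            # bool, same shape as the image
    center_px: tuple[float, float]
    equiv_diameter_mm: float
    energy: float               # quantized cut energy of the labelling

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TumorModel:
    """Sphere approximation of the tumor (centre in camera frame, mm)."""

    center: np.ndarray
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("tumor diameter must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


def init_labels(
    shape: tuple[int, int], seed: SeedInit, calib: ProbeCalibration
) -> LabelMask:
    """Rasterise the seed geometry into a trimap.

    Radii given in mm are converted to pixels with the x pixel spacing
    (isotropic imaging assumed; with anisotropic spacing the disk becomes an
    ellipse in pixel space, rasterised accordingly).
    """
    h, w = shape
    cx, cy = seed.center_px
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"seed centre {seed.center_px} outside image {w}x{h}")
    sx, sy = calib.pixel_spacing
    yy, xx = np.mgrid[0:h, 0:w]
    # metric distance from the click, honouring anisotropic spacing
    r_mm = np.hypot((xx - cx) * sx, (yy - cy) * sy)
    r_fg = seed.diameter_mm / 2.0
    labels = np.zeros(shape, dtype=np.uint8)
    labels[r_mm <= r_fg + seed.ring_margin_mm] = PROBABLE_FG
    labels[r_mm <= r_fg] = DEFINITE_FG
    if not np.any(labels == DEFINITE_FG):
        # degenerate sub-pixel disk: keep at least the clicked pixel
        labels[int(round(cy)), int(round(cx))] = DEFINITE_FG
    return LabelMask(labels)


def _histogram_model(values: np.ndarray, bins: int) -> np.ndarray:
    """Laplace-smoothed intensity histogram -> per-bin probabilities."""
    hist, _ = np.histogram(values, bins=bins, range=(0.0, 256.0))
    probs = (hist + 1.0) / (hist.sum() + bins)
    return probs


def _bin_index(image: np.ndarray, bins: int) -> np.ndarray:
    idx = np.clip((image.astype(float) / 256.0 * bins).astype(int), 0, bins - 1)
    return idx


@dataclass
class GraphCutProblem:
    """Quantized min-cut instance: integer data and pairwise terms.

    ``data_fg[p]`` / ``data_bg[p]`` are the costs of labelling pixel ``p``
    foreground / background; ``pair`` lists (i, j, weight) for the Potts
    boundary term.  ``hard_fg`` / ``hard_bg`` pixels are constrained.
    The energy of a labelling is the sum of its unary costs plus the weight
    of every edge cut by the labelling.
    """

    shape: tuple[int, int]
    data_fg: np.ndarray     # int64, flat
    data_bg: np.ndarray     # int64, flat
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_w: np.ndarray      # int64
    hard_fg: np.ndarray     # bool, flat
    hard_bg: np.ndarray     # bool, flat

    def energy(self, mask: np.ndarray) -> int:
        """Exact quantized energy of a binary labelling (True = foreground)."""
        lab = np.asarray(mask).reshape(-1).astype(bool)
        if np.any(lab[self.hard_bg]) or not np.all(lab[self.hard_fg]):
            return np.iinfo(np.int64).max  # violates a hard constraint
        unary = np.where(lab, self.data_fg, self.data_bg).sum()
        cut = self.pair_w[lab[self.pair_i] != lab[self.pair_j]].sum()
        return int(unary + cut)

    def solve(self) -> np.ndarray:
        """Minimum-energy labelling via max-flow; True = foreground."""
        n = self.data_fg.size
        src, snk = n, n + 1
        big = np.int64(1) << 50

        # s-t capacities: source->p costs data_bg if cut (p on sink side)...
        # Standard construction: cap(source->p) = data_bg[p] (pay when p is
        # background... we pay data_fg when labelled fg). Use: edge s->p with
        # capacity data_bg, p->t with capacity data_fg; p on source side
        # (foreground) cuts p->t paying data_fg.
        cap_s = self.data_bg.astype(np.int64).copy()
        cap_t = self.data_fg.astype(np.int64).copy()
        cap_s[self.hard_fg] = big
        cap_t[self.hard_bg] = big

        rows = np.concatenate([
            np.full(n, src), np.arange(n),
            self.pair_i, self.pair_j,
        ])
        cols = np.concatenate([
            np.arange(n), np.full(n, snk),
            self.pair_j, self.pair_i,
        ])
        data = np.concatenate([cap_s, cap_t, self.pair_w, self.pair_w]).astype(np.int64)
        keep = data > 0
        graph = sparse.csr_matrix(
            (data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2), dtype=np.int64
        )
        graph.sum_duplicates()
        if graph.max() >= np.iinfo(np.int32).max:
            # the solver works on int32 internally; rescale hard-constraint caps
            big32 = np.int64(np.iinfo(np.int32).max // 4)
            graph.data = np.minimum(graph.data, big32)
        graph = graph.astype(np.int32)
        res = maximum_flow(graph, src, snk)
        residual = graph - res.flow
        residual.data = np.maximum(residual.data, 0)
        reach = breadth_first_order(
            (residual > 0).astype(np.int8), src, directed=True, return_predecessors=False
        )
        fg = np.zeros(n, dtype=bool)
        reach = reach[reach < n]
        fg[reach] = True
        return fg.reshape(self.shape)


def build_graph_cut(
    image: np.ndarray, labels: LabelMask, config: SegmentationConfig
) -> GraphCutProblem:
    """Assemble the quantized min-cut instance for an image and trimap."""
    img = np.asarray(image, dtype=float)
    lab = labels.labels
    if img.shape != lab.shape:
        raise ValueError("image and label mask shapes differ")
    if config.presmooth_sigma > 0:
        img_d = ndimage.gaussian_filter(img, config.presmooth_sigma)
    else:
        img_d = img

    fg_px = img_d[lab == DEFINITE_FG]
    bg_px = img_d[lab == BACKGROUND]
    if bg_px.size == 0:
        bg_px = img_d.ravel()  # ring covers the whole image: fall back to global stats
    p_fg = _histogram_model(fg_px, config.bins)
    p_bg = _histogram_model(bg_px, config.bins)
    # distinguishability check on the raw (unsmoothed) histograms, so that
    # small seed regions are not diluted by the Laplace prior
    h_fg, _ = np.histogram(fg_px, bins=config.bins, range=(0.0, 256.0))
    h_bg, _ = np.histogram(bg_px, bins=config.bins, range=(0.0, 256.0))
    overlap = float(
        np.minimum(h_fg / max(h_fg.sum(), 1), h_bg / max(h_bg.sum(), 1)).sum()
    )
    if overlap >= config.overlap_warn_limit:
        warnings.warn(
            f"foreground/background intensity models overlap {overlap:.2f}: "
            "segmentation may be unreliable",
            stacklevel=3,
        )

    idx = _bin_index(img_d, config.bins).ravel()
    cost_fg = -np.log(p_fg[idx])
    cost_bg = -np.log(p_bg[idx])
    flat_lab = lab.ravel()
    if not config.background_hard:
        cost_fg = cost_fg + config.background_soft_penalty * (flat_lab == BACKGROUND)

    # contrast-weighted Potts links
    h, w = img.shape
    pix = np.arange(h * w).reshape(h, w)
    pairs = [
        (pix[:, :-1].ravel(), pix[:, 1:].ravel()),
        (pix[:-1, :].ravel(), pix[1:, :].ravel()),
    ]
    if config.connectivity == 8:
        pairs.append((pix[:-1, :-1].ravel(), pix[1:, 1:].ravel()))
        pairs.append((pix[:-1, 1:].ravel(), pix[1:, :-1].ravel()))
    elif config.connectivity != 4:
        raise ValueError("connectivity must be 4 or 8")
    pi = np.concatenate([p[0] for p in pairs])
    pj = np.concatenate([p[1] for p in pairs])
    flat = img_d.ravel()
    diff2 = (flat[pi] - flat[pj]) ** 2
    beta = 1.0 / max(2.0 * diff2.mean(), 1e-12)
    dist = np.where(np.arange(pi.size) < pairs[0][0].size + pairs[1][0].size, 1.0, np.sqrt(2.0))
    wgt = config.smoothness * np.exp(-beta * diff2) / dist

    q = lambda x: np.round(np.asarray(x) * _CAP_SCALE).astype(np.int64)
    return GraphCutProblem(
        shape=img.shape,
        data_fg=q(cost_fg),
        data_bg=q(cost_bg),
        pair_i=pi.astype(np.int64),
        pair_j=pj.astype(np.int64),
        pair_w=q(wgt),
        hard_fg=(flat_lab == DEFINITE_FG),
        hard_bg=np.zeros(flat_lab.size, dtype=bool) if not config.background_hard
        else (flat_lab == BACKGROUND),
    )


def _finish(
    mask: np.ndarray,
    labels: LabelMask,
    calib: ProbeCalibration,
    energy: float,
) -> SegmentationResult:
    """Post-process: keep the component(s) carrying definite-fg seeds; derive stats."""
    comp, n_comp = ndimage.label(mask)
    if n_comp > 1:
        seed_comp = np.unique(comp[(labels.labels == DEFINITE_FG) & (comp > 0)])
        if seed_comp.size:
            mask = np.isin(comp, seed_comp)
        else:
            mask = comp == np.bincount(comp[comp > 0]).argmax()
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("segmentation produced an empty mask")
    sx, sy = calib.pixel_spacing
    area_mm2 = ys.size * sx * sy
    return SegmentationResult(
        mask=mask.astype(bool),
        center_px=(float(xs.mean()), float(ys.mean())),
        equiv_diameter_mm=2.0 * np.sqrt(area_mm2 / np.pi),
        energy=float(energy),
    )


def graph_cut_segment(
    image: np.ndarray,
    labels: LabelMask,
    calib: ProbeCalibration,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Minimum-cut binary segmentation under the trimap's constraints."""
    config = config or SegmentationConfig()
    problem = build_graph_cut(image, labels, config)
    mask = problem.solve()
    return _finish(mask, labels, calib, problem.energy(mask))


def refine_click(
    image: np.ndarray,
    current: SegmentationResult,
    labels: LabelMask,
    click_px: tuple[float, float],
    calib: ProbeCalibration,
    config: SegmentationConfig | None = None,
) -> tuple[SegmentationResult, LabelMask]:
    """One correction click: add the area if clicked outside the mask, remove
    it if clicked inside, then re-run the cut.  Returns the new result and
    the updated trimap (feed it back in for subsequent clicks)."""
    config = config or SegmentationConfig()
    h, w = image.shape
    cx, cy = click_px
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError(f"click {click_px} outside image {w}x{h}")
    sx, sy = calib.pixel_spacing
    yy, xx = np.mgrid[0:h, 0:w]
    region = np.hypot((xx - cx) * sx, (yy - cy) * sy) <= config.refine_radius_mm

    inside = bool(current.mask[int(round(cy)), int(round(cx))])
    new_labels = labels.labels.copy()
    if inside:
        new_labels[region] = BACKGROUND
    else:
        new_labels[region] = DEFINITE_FG
    lm = LabelMask(new_labels)
    problem = build_graph_cut(image, lm, config)
    if inside:
        # removal: the clicked region must not come back as foreground
        problem.hard_bg = problem.hard_bg | region.ravel()
    mask = problem.solve()
    return _finish(mask, lm, calib, problem.energy(mask)), lm


def mask_to_tumor_model(
    seg: SegmentationResult, frame: TrackedFrame, calib: ProbeCalibration
) -> TumorModel:
    """Lift the 2D mask to a 3D sphere model.

    The frame is assumed to show the tumor's largest diameter (the operator
    freezes the midsection slice), so the mask centroid maps to the sphere
    centre and the equal-area circle diameter to the sphere diameter.
    """
    if seg.area_px == 0:
        raise ValueError("cannot build a tumor model from an empty mask")
    center = pixel_to_world(frame, calib, seg.center_px)
    return TumorModel(center=center, diameter_mm=seg.equiv_diameter_mm)
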