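# Methods

This note documents the models, conventions and numerical choices behind
`sononav`, and what the synthetic phantom does and does not emulate.

## Coordinate chain and conventions

All 3D quantities are millimetres in a right-handed frame. A pixel `(u, v)`
of a tracked frame maps to the camera frame through

```
p_world = C_T_MS · MS_T_US · T_scale · (u, v, 0, 1)ᵀ
```

where `C_T_MS` is the per-frame camera←marker-shield pose, `MS_T_US` the
fixed probe calibration and `T_scale = diag(sx, sy, 1, 1)` the pixel
spacing. Image convention: pixel (0, 0) is top-left, +x lateral (right),
+y axial (down, increasing depth), the image lives in the z = 0 plane of
the US frame. Rigid transforms are stored as full 4×4 matrices and
validated (orthonormal rotation, det +1, tolerance 1e-9) rather than as
quaternion+vector pairs, mirroring the chained-product form of the
acquisition loop. Calibration estimation (z-wire) and temporal probe/tracker
synchronisation are out of scope; the calibration is an input.

## Contact classification

Features are the minimum, maximum, mean, standard deviation and kurtosis of
the top `floor(H/3)` image rows — the band directly under the transducer
face, where loss of capsule contact shows first. Kurtosis uses the Fisher
(excess) convention; a zero-variance band maps to 0 with a warning, and the
convention is stored in the persisted model so training and prediction
cannot silently disagree. The classifier is an RBF-kernel SVM (C = 10,
gamma = "scale") on standardised features. The model object holds its
decision function explicitly (support vectors, dual coefficients,
intercept, scaler statistics), oriented at training time so positive means
"contact"; persistence is a plain NPZ archive with a JSON metadata block —
no pickling. Real devices apply automatic gain; the phantom emulates this
by renormalising the mean brightness of contact frames, so the classifier
separates classes on band structure rather than absolute gain.

## Surface scanning and the LOF filter

The acquisition loop processes frames in order. A no-contact frame clears
the candidate buffer, so separate sweep segments can never contaminate each
other's density estimates. A contact frame contributes the world position
of the *top-row midpoint* of the image (the capsule contact line under the
transducer centre; configurable). Candidates enter a FIFO buffer of the
last `W = 10` points; once at least `k + 1` points are buffered
(`k = min(9, |buffer| − 1)`), the incoming point's local outlier factor
against the buffer is computed and the point joins the cloud iff
`LOF ≤ τ`, default `τ = 1.5`.

The LOF follows the original definition exactly: k-distance neighbourhoods
with ties included, reachability distances, local reachability density, and
the neighbour/query density ratio. Inliers score ≈ 1 and fluctuate around
1, which is why the acceptance threshold sits above 1: a cut at exactly 1
would reject roughly half of genuine inliers. Config presets `paper_prose`
(accept iff < 1) and `paper_pseudocode` (accept iff > 1) preserve the two
stricter printed variants of this rule for auditing; they are not defaults
because both conflict with LOF semantics. Points rejected by the filter
still pass through the buffer (the buffer reflects what was acquired, not
what was kept), which means two *adjacent* identical glitches can shield
each other — the 100 % rejection guarantee applies to isolated glitches,
the tracking-failure mode the filter exists for.

Surface reconstruction treats the cloud as an oriented sample of an open
surface patch: points are projected onto their principal (PCA) plane,
Delaunay-triangulated in that chart, slivers dropped, and faces oriented
towards the side the probe scanned from (the mean opposite of the image
depth axis; +z if no hint is available). This suits the height-field-like
patches a liver sweep produces; it does not close holes or handle
self-occluding geometry, which matches the single-sided access of an
intra-operative scan.

## Graph-cut segmentation

The trimap from the operator's click: a disk of the chosen diameter is
*definite foreground* (hard constraint), the annulus out to
`ring_margin_mm` (default 20 mm) is *probably foreground* (free), and
everything outside is background — soft-seeded by default (a constant
penalty of 1.5 −log-units on their foreground cost) because hard background
would forbid legitimate mask growth beyond the ring. Distances are
converted mm→px per axis, so anisotropic spacing rasterises ellipses.
Sub-pixel disks keep at least the clicked pixel.

Data terms are −log likelihoods under 32-bin Laplace-smoothed intensity
histograms fitted to the definite-foreground disk and the background
region; the image is pre-smoothed with a σ = 1.5 px Gaussian for the data
term only, which tames Rayleigh speckle without moving boundaries
materially. The boundary term is a contrast-weighted Potts on the 4-connected
grid, `λ·exp(−β(Iₚ−I_q)²)` with `β = 1/(2·mean ΔI²)` and λ = 6 by default.
A warning is raised when the raw foreground/background histograms overlap
≥ 0.85 (computed unsmoothed so small seeds are not diluted); the result is
still returned.

Energies are quantized to integers (scale 1e4) and the minimum cut is
solved as max-flow on the pixel grid; hard constraints are edges of
effectively infinite capacity. The returned labelling provably minimises
the quantized energy — verified in the tests by exhaustive enumeration on
instances with ≤ 16 free pixels. Post-processing keeps the connected
component(s) containing definite-foreground seeds; after a refinement
click adds a disconnected lobe, that lobe is itself seeded and therefore
kept, so a refined mask may legitimately have more than one component.

A correction click re-seeds a 3 mm-radius neighbourhood: as background if
the click falls inside the current mask (removal), as definite foreground
otherwise (addition) — the add/remove decision is exactly membership of the
click in the current mask — and the cut is re-run on the updated trimap.
Clicking the same point twice approximately restores the previous mask.

The tumor's 3D model is a sphere: centre = the mask centroid lifted through
the pixel-to-world chain of the frozen frame, diameter = the equal-area
circle diameter. This single-slice approximation is deliberate (the frozen
frame is chosen at the tumor's largest diameter) and is the dominant,
irreducible error source for irregular lesions; multi-slice fusion is out
of scope.

## Conical resection planning

Let `r_t` be the tumor radius, `m` the safety margin, `R = r_t + m` the
margin-sphere radius and `θ` the cone half-angle (default 45°, a free
design parameter of the original workflow that is deliberately exposed).
The axis points from the tumor centre to the exact closest point on the
surface mesh (point-to-triangle distance over all faces; ties broken by
lowest face index). For an apex at distance `h` below the centre along the
axis, the distance from the centre to the cone's lateral surface is
`h·sin θ`, so the minimal tangent depth is `h = R / sin θ`, floored at
`R +` a 2 mm clearance so the apex always sits below the margin sphere.
The achieved clearance `h·sin θ − r_t` is checked against `m` to 1e-6 mm at
construction. An optional maximum depth turns an over-narrow cone into an
error that names the minimal feasible half-angle. The tumor must be
strictly interior: centre-to-surface distance above `r_t` and on the inner
side of the closest face's outward normal.

The resection line is extracted by root-finding the cone's implicit
function `ρ − z·tan θ` along every mesh edge whose endpoints straddle it
(Brent's method, so each vertex lies exactly on a mesh edge and on the cone
to solver tolerance), then ordering crossings by azimuth about the axis.
"The resection line" here is the entire closed intersection curve — the
line the surgeon draws — not a single starting point.

Overlay projection intersects each planned structure with a frame's image
plane: spheres analytically (circle of radius `√(r² − d²)` at plane
distance `d`), the cone by contouring its implicit function on a pixel
grid, and resection-line vertices within one pixel spacing of the plane as
point marks. Contours are clipped to the image; empty intersections leave
empty contour lists with per-structure visibility flags intact.

## Margin measurement and the R0 rule

The tumor mesh is subdivided until no edge exceeds 0.5 mm, and every vertex
is assigned its exact distance to the specimen surface (vectorised
point-to-triangle with a KD-tree bound that is provably conservative, so
results equal brute force). The *minimum* over vertices is the resection
margin — a minimum-based definition because a single close approach is what
leaves tumor at the cut surface — and the full distribution (median,
per-vertex list) is reported alongside. If the specimen is watertight and
any tumor vertex lies outside it, the margin is 0 and the case R1; open
specimens raise a warning and skip the containment check. R0 requires
`min margin > threshold` strictly (default 1.0 mm): exactly 1.0 mm is R1.
Distances are taken to the whole specimen boundary, including the intact
liver-surface cap, not only the cut surface — for shallow tumors the two
differ (see phantom notes). Cohort summaries use linear-interpolation
(Hyndman–Fan type 7) quantiles.

## The synthetic phantom

The phantom reproduces the *study conditions* of an ex-vivo bench
evaluation: tumor-mimic diameters N(12.1, 2.5) mm truncated above 4 mm,
centre depths uniform in 10–20 mm below the local surface, ≥ 10 mm
clearance between mimics, hyperechoic appearance. The surface is a
Gaussian-filtered random heightfield (amplitude 3 mm, correlation length
20 mm over a 140 mm phantom). B-mode rendering is appearance-level only:
multiplicative Rayleigh speckle, lesion pixels brightened by the contrast
ratio (default 2.0), mild exponential depth attenuation, auto-gain
normalisation for contact frames, and a dark noise band for no-contact
frames. It is *not* a wave-propagation simulation — no shadowing,
refraction, anisotropic speckle or real transducer PSF — so passing tests
show geometric and statistical consistency of the pipeline, not robustness
to every artefact of real B-mode imaging. Imaging geometry defaults
(60 × 50 mm field at 0.2 mm/px) are arbitrary documented choices.

Sweeps glide the probe along a serpentine path with the image plane
vertical and the top-row midpoint on the surface; poses receive Gaussian
noise (0.2 mm, 0.1°) and scheduled lift-off blocks produce the exact
configured no-contact fraction. In-silico resection cuts the planned cone
out of the phantom: the specimen mesh is the cone's lateral surface up to
the true liver surface plus the enclosed surface cap, watertight. Execution
noise displaces the lateral cut along its outward normal by a smooth random
field on the (azimuth, height) parameterisation — Gaussian-filtered white
noise, periodic in azimuth, tapered to zero at the apex and the surface rim
— mimicking coherent surgical deviation rather than per-vertex jitter. A
noisy cut crossing the tumor is returned as-is and classified R1
downstream; that is the phenomenon under study, not an error.

Margin-recovery experiments (`insilico` module) place tumors at 18–20 mm
depth with diameters capped at 13 mm so that the *cut* surface is the
closest specimen boundary; with shallower tumors the minimum distance would
measure the intact parenchyma above the tumor, which the knife never
touched. The generator's general defaults are unchanged by this. The
simulated operator centres the probe over the lesion for the frozen frame,
clicks within 2 px of the true centre, and guesses the diameter within
±10 % — replayable stand-ins for the interactive steps. Problem sizes in
the tests and acceptance script (500-frame sweeps, 20-seed end-to-end runs,
15 seeds per noise level) are chosen to estimate each property stably while
keeping a full run in the minutes range.

## Known limitations

- Single-slice sphere tumor model; irregular lesions are underserved by
  construction.
- Reconstruction assumes a chart-like (single-valued) surface patch.
- The quantized cut is optimal for the integer energy; ties may differ from
  the real-valued optimum by sub-1e-4 energy units.
- The cone is a full cone with a configurable half-angle; whether a
  truncated frustum or another aperture rule better matches any particular
  clinical device is not claimed.
- No tissue deformation, shrinkage or vessel awareness anywhere in the
  pipeline.
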