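# sononav

Intra-operative, ultrasound-only planning and navigation geometry for
non-anatomical (atypical) liver resections.

## The problem

In a non-anatomical resection only the tumor plus a safety margin (typically
5–10 mm) is removed, sparing healthy parenchyma — but without anatomical
landmarks it is hard to keep a negative (R0, > 1 mm) margin while cutting
blind through tissue. Image-guidance systems built on pre-operative CT/MRI
struggle with registration and organ deformation. The approach implemented
here sidesteps registration entirely: the surgical plan is built *on the
spot* from navigated intra-operative ultrasound alone.

`sononav` is a tested re-implementation of that computational pipeline,
exercised end-to-end on synthetic phantoms with known ground truth. It is
aimed at researchers in image-guided surgery who want a reproducible,
hardware-free reference for each stage:

1. **Surface scanning** — for each tracked B-mode frame, an SVM on five
   intensity statistics of the upper third of the image (min, max, mean,
   standard deviation, excess kurtosis) decides whether the transducer has
   capsule contact. Contact frames contribute one surface point through the
   calibrated chain `p = C_T_MS · MS_T_US · T_scale · p_pixel`; a point is
   accepted only if its **local outlier factor** against the last 10 points
   stays near 1, and the buffer clears on every contact loss. The accepted
   cloud is triangulated into the liver surface mesh.
2. **Tumor segmentation** — on a frozen midsection frame the operator clicks
   the tumor centre and picks an approximate diameter; a disk becomes
   *definite foreground*, a 20 mm annulus *probably foreground*, and a
   contrast-weighted min-cut (**graph cuts**) produces the mask. Single
   clicks add or remove mis-segmented areas; the mask's centroid and
   equal-area diameter define a sphere model of the tumor.
3. **Resection planning** — the tumor sphere is inflated by the safety
   margin *m*; a cone is aimed from the tumor at the closest surface point
   with its apex at depth `h = (r_t + m) / sin θ` below the centre, which
   makes the lateral surface exactly tangent to the margin sphere. The
   **resection line** is the closed curve where the cone crosses the liver
   mesh; all planned structures can be projected back onto any tracked
   frame as overlay contours.
4. **Margin analysis** — given tumor and specimen meshes, the exact 3D
   point-to-surface distance distribution is computed and the case is
   classified **R0 iff the minimum margin > 1 mm** (strict).
5. **Synthetic phantom** — generates everything above with ground truth:
   smooth random liver surfaces, spherical tumor mimics (diameters
   N(12.1, 2.5) mm, depths 10–20 mm), Rayleigh-speckle B-mode frames with
   hyperechoic lesions, tracked sweeps with pose noise and probe lift-offs,
   and in-silico resections with coherent execution noise.

## A worked example

```bash
python examples/05_virtual_resection.py
```

```
true tumor:      diameter 12.0 mm at [ 71.8  74.4 -19.4] mm
estimated tumor: diameter 12.4 mm at [ 71.8  74.4 -19.7] mm
centre error: 0.22 mm
planned safety margin: 10.0 mm
achieved minimum margin: 10.35 mm -> R0
median margin over the tumor surface: 12.13 mm
```

Every stage ran on *estimated* quantities — the scanned (not true) surface
and the segmented (not true) tumor — while the final margin is measured
against the phantom's true tumor, so the 0.35 mm discrepancy is the
accumulated error of the entire method. The other examples
(`examples/01_…` to `04_…`) demonstrate scanning, segmentation, cone
fitting and margin measurement individually.

The `sononav` command exposes the same stages as subcommands
(`simulate`, `train-contact`, `scan`, `segment`, `plan`, `measure`,
`run-all`); see `sononav --help`.

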