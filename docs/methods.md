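# Methods

This note documents the models, conventions and numerical choices behind
`nac3d`, and what the synthetic phantoms do and do not establish.

## Geometry model

All measurements are made in world millimetres in a RAS frame (+x right,
+y anterior, +z superior). Volumes are stored with an axis-aligned affine:
per-axis spacing, the world position of voxel (0,0,0) (voxel centers, 0-based
indices), and axis codes giving the anatomical direction of increasing index.
`canonicalize` permutes/flips grids to a fixed convention (axis 0
superior→inferior, axis 1 posterior→anterior, axis 2 left→right) without
moving any voxel in world space. Because the T2 and DCE volumes may be
sampled differently (sagittal 3 mm T2 vs axial DCE), **no resampling or
registration is performed**: the NAC base point comes from the T2 grid, the
lesion boundary from the DCE grid, and the distance is taken between world
points. This presumes the two acquisitions share a patient coordinate frame
(same examination, no inter-sequence motion); motion between sequences is a
known, unmodelled error source.

Oblique acquisitions (non-axis-aligned affines) are rejected with an
orientation error rather than silently approximated. DICOM series are read
with explicit consistency checks (single series UID, uniform inter-slice
spacing to 0.1%), so a missing slice is a hard geometry error.

## NAC segmentation

* **Body mask**: Otsu threshold, largest 26-connected component, hole fill.
  A minimal standard recipe; adequate because only the anterior surface and
  a growth constraint are needed from it.
* **Seeding**: per breast (lateral half of the grid), the most anterior
  body voxel is the nipple apex candidate; the seed group is that voxel plus
  its 8-connected in-plane neighbours inside the body (≤ 9 seeds). When the
  anterior face is flat at voxel resolution the tie is resolved to the
  candidate nearest the tie-set centroid, then to the smallest index triple —
  deterministic, and orientation-independent after canonicalisation. A
  warning accompanies any tie.
* **Region growing** runs in 3D on the T2 volume (seeds are found via the
  axial MIP, but the base point must be a 3D point): voxel `v` is admissible
  iff `|I(v) − m| ≤ t·m` with `m` the mean seed intensity and `t = 0.5` by
  default; the mask is the union of admissible 26-connected components
  containing seeds, i.e. exactly a breadth-first flood fill (verified
  against one in the tests). The growth is monotone in `t` by construction.
  `t = 0` is rejected (the limit `t → 0⁺` keeps only voxels at exactly the
  seed intensity); a zero-intensity seed is a degenerate-seed error.
* **Base curve**: the "inner edge" is extracted per lateral column of the
  axially projected mask as the most posterior mask voxel, lifted back to 3D
  at the mean superior position of the mask voxels in that posterior row.
  The ordered edge points are smoothed by cubic B-splines in `y(x)` and
  `z(x)` (`scipy.interpolate.splrep`, smoothing factor = number of points by
  default — enough to damp single-voxel stair-stepping without detaching
  from the mask). The **base-center point** is the sample at the arc-length
  midpoint of the densely sampled curve (512 samples, with sub-segment
  interpolation). Fewer than 4 edge columns is a degenerate-curve error.
* **QC flags**: `empty_mask`, `base_curve_degenerate` (blocking — distance
  computation refuses), `mask_touches_image_border` (warning only). This
  mirrors the failure accounting of nipple segmentation in clinical use
  (malpositioned or inverted nipples are out of scope beyond flagging).

## Lesion segmentation

* **Breast mask**: body mask clipped anterior to an estimated chest-wall
  plane, taken where the per-slice body cross-sectional area last stays
  within 95% of its maximum (the chest section is large and flat; the breast
  mound tapers). This is a deliberately simple estimator; it is exercised
  only on phantom-like geometry.
* **Vessel reference**: strongly enhancing (`RE ≥ 1.0`), elongated
  (principal-axis ratio ≥ 5) and small (< 0.5 mL) components are vessels;
  the reference is the mean post-contrast intensity over them. Without any
  vessel, the 99.5th percentile of post-contrast breast intensity is used,
  with a warning.
* **Relative enhancement**: pre and post frames are divided by the vessel
  reference, then `RE = (post − pre)/max(pre, ε)` with
  `ε = 10⁻³ × median(pre > 0)` (scaled with the reference), making the
  thresholded map invariant to global scanner gain — the stated purpose of
  vessel normalisation. Default frame: the second post-contrast frame.
  Threshold: `RE ≥ 0.5`.
* **Candidates** are 26-connected components with world-mm descriptors:
  volume, centroid, anterior-most point (ties to the smallest index triple),
  elongation from the second-moment principal axes (regularised with the
  single-voxel extent `spacing²/12`, so one voxel has elongation 1), border
  contact, mean RE. **False-positive reduction** removes candidates below
  0.05 mL, above elongation 5, or touching the grid border; it is a pure,
  idempotent filter. Selection defaults to the most anterior candidate —
  the automated stand-in for the one manual step of the clinical procedure —
  with an explicit index as the alternative.

The specific threshold values are reconstructions of an under-documented
clinical system and are all exposed as configuration.

## Distance

`d₃D = min_b ‖c − b‖` over the lesion's boundary-voxel centers (voxels with
a 6-neighbour outside the mask); exact ties resolve to the smallest voxel
index triple. When the base point is outside the mask this equals the
minimum over *all* voxel centers (verified exhaustively in tests); if the
base point falls inside the lesion the distance is clamped to 0 with a
warning — the only monotone-consistent choice. Sub-voxel surface
interpolation is deliberately not attempted: endpoints are voxel centers,
which bounds the discretisation error by about one voxel diagonal and
matches the resolution at which cut-offs are clinically quoted.

The 2D MIP emulation drops the superior–inferior world coordinate of both
endpoints before minimising, from the same base point, so the 2D/3D
comparison isolates the projection effect; `d₂D ≤ d₃D` holds identically
(including the inside-lesion clamp, applied to both).

## Diagnostics

* Positive call: `distance ≤ cutoff` (matching how published cut-off columns
  are labelled). The strict `<` reading that the prose definition of a true
  positive suggests is available as `convention="lt"`; the choice is a
  visible switch because the two differ exactly at the cut-off value.
* Metrics are reported to one decimal of a percent, confidence bounds to
  integer percent, both with **half-up rounding** (what printed tables use;
  banker's rounding changes e.g. 56.25 → 56.2).
* CIs are exact Clopper–Pearson from beta quantiles (cross-checked against
  `statsmodels`' beta interval).
* ROC thresholds are all observed distances plus the call-nothing extreme;
  the trapezoidal AUC then equals the Mann–Whitney concordance probability
  with ties counted ½ (asserted to 1e-9 against a pairwise oracle). The best
  cut-off maximises Youden's J, ties toward the smaller cut-off. Under the
  default `≤` convention a perfectly separated cohort returns the largest
  involved distance; under `<` it returns the smallest uninvolved distance.
* The paired AUC comparison is DeLong's test (midrank algorithm). The
  literature this tool evaluates against names no method; DeLong is the
  standard paired choice and its type-I error is verified by simulation
  (null rejection rate within [0.03, 0.07] at α = 0.05 over 1000 seeded
  replicates with n = 100, correlated methods). `reconstruct_table`
  inverts printed sensitivity/specificity percentages into the unique
  integer 2×2 table given class sizes, erroring when no or multiple integers
  re-round to the printed value.

## Phantoms

The generator emulates a prone axial breast acquisition: posterior chest
slab, half-ellipsoid breast mound (default radii 35×45×35 mm on a 96 mm,
1 mm-isotropic grid), a protruding NAC bump whose posterior face is the
tangent plane at the breast apex, a spherical/ellipsoidal lesion, and
tubular vessels. Baselines: air 0, tissue 100, NAC 300 on T2. DCE is
wash-in only: post = pre × (1 + A) inside enhancing structures, constant
across the (default 6) post frames at 70 s nominal temporal resolution;
default lesion amplitude A = 1.5, vessel amplitude 3.5 (≥ 2× the lesion, so
vessel detection and false-positive reduction are genuinely exercised).
Noise is additive Gaussian, seeded, drawn in a fixed order for bit-exact
reproducibility; Rician statistics are not modelled — at the low noise
levels exercised (≤ 5% of the lesion enhancement) the thresholded,
ratio-based pipeline is insensitive to the distinction.

Ground truth is closed form: the NAC base-center is the bump's base-center
point (by default the breast apex) and the distance is the exact
point-to-ellipsoid minimum (Lagrange condition solved by bracketed root
finding; verified against 10⁶-point surface sampling to < 0.05 mm and
clamped to 0 for interior points).

A `clinical_spec()` profile reproduces a typical acquisition geometry
(axial DCE at 0.7865 × 0.7865 × 3 mm; sagittal T2 at 0.8536 × 0.8536 ×
3 mm on its own grid) so the mixed-orientation, mixed-resolution path is
tested; the fast 96³ isotropic profile is the default for tests and the
acceptance script, with 20 noiseless + 20 noisy seeded geometries
(randomised lesion position/size, nipple shape, vessel position).

**What phantom results do not show**: real parenchymal texture,
non-mass-like enhancement, motion, bias fields, inverted nipples, or
T2/DCE misregistration. Passing phantom recovery demonstrates the geometry
and numerics of the pipeline, not clinical segmentation performance.

## Known limitations

* The chest-wall estimator and Otsu body mask are tuned to phantom-like
  contrast; clinical data would need the documented thresholds revisited.
* Distances are straight-line Euclidean, as in the measurement this
  automates — not geodesic through tissue.
* Cohort-level clinical quantities (AUCs near 0.72–0.77, paired p-values)
  depend on patient data that is not distributable; the package verifies
  the statistical machinery (worked examples, exact intervals, calibration)
  rather than re-deriving cohort results.
* Two derived cells of the published validation table (NPV at the 10 mm
  automated cut-off and accuracy at the 20 mm automated cut-off) are
  arithmetically inconsistent with their own printed
  sensitivity/specificity and class sizes by 0.1; the package reports the
  values implied by the unique integer tables (74.2, 69.4).
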