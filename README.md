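# nac3d

Automated 3D tumour-to-nipple-areola-complex (NAC) distance measurement on
breast DCE-MRI, with synthetic phantoms carrying analytic ground truth and a
diagnostic-performance evaluation layer.

## The problem

When a breast-cancer patient is a candidate for nipple-sparing mastectomy,
the surgeon needs to know whether the nipple harbours occult tumour. The
single best imaging predictor is the **tumour-to-NAC distance**: the minimum
distance between the base of the NAC and the nearest tumour margin on
preoperative MRI. Measured manually with calipers on an axial
maximum-intensity projection (MIP), the distance is operator-dependent and —
because the projection discards one spatial axis — systematically
underestimated: lesion and nipple can look adjacent while sitting in
different slices.

`nac3d` implements a fully automated 3D alternative:

1. **NAC segmentation** (T2-weighted volume): the nipple is located at the
   most anterior point of the body region; seeds there drive intensity
   region growing (voxels within ±50% of the seed intensity,
   26-connectivity) to segment the NAC. The posterior ("inner") edge of the
   NAC mask is smoothed with a cubic B-spline and the curve's arc-length
   midpoint becomes the single base-center point.
2. **Lesion segmentation** (DCE series): the breast area is masked on the
   pre-contrast frame, the post-contrast frames are normalised with the
   signal intensity of automatically detected mammary vessels, the relative
   enhancement map `RE = (S_post − S_pre) / S_pre` is thresholded
   (default RE ≥ 0.5), and connected components are filtered by volume,
   elongation and border contact to suppress vessels and artefacts. The most
   anterior surviving candidate is selected by default.
3. **Distance**: the automated measurement is
   `d₃D = min_b ‖c − b‖` over lesion boundary-voxel centers `b`, with `c`
   the NAC base-center point, in world millimetres. The manual method is
   emulated as the same minimum after dropping the superior–inferior
   coordinate (`d₂D ≤ d₃D` always).
4. **Evaluation**: distances against pathology labels — 2×2 tables at
   clinical cut-offs (5/10/20/30 mm, positive call `d ≤ cutoff`),
   sensitivity/specificity/PPV/NPV/accuracy with exact Clopper–Pearson 95%
   intervals, ROC with Mann–Whitney AUC, Youden-optimal cut-off, and
   DeLong's paired test for comparing two methods on the same patients.

No clinical images ship with the package: the `phantom` module generates
T2 + DCE breast phantoms (half-ellipsoid breast, protruding nipple,
spherical/ellipsoidal enhancing lesion, tubular vessels, Gaussian noise)
whose true NAC base point and tumour-to-NAC distance are known in closed
form, so the whole pipeline is testable end to end.

## Worked example

```sh
$ nac3d phantom --out demo --seed 0
phantom written to demo (truth distance 19.00 mm, 10 files)

$ nac3d segment-nac --t2 demo/t2.nii.gz --out demo_nac
NAC base point: [47.5, 65.0, -47.5] mm

$ nac3d run --case demo --out demo_out
auto_3d 20.01 mm, mip_2d 20.01 mm
```

The default phantom places a 6 mm-radius lesion 25 mm posterior of the NAC
base point, so the analytic distance is 25 − 6 = 19.0 mm. The pipeline
reports 20.01 mm: the base point is recovered exactly ([47.5, 65.0, −47.5]
is the true apex), and the ~1 mm excess is voxel quantisation — distance
endpoints are voxel centers, and no voxel center sits exactly on the
lesion's anterior pole. Recovery is always within one voxel diagonal
(√3 mm at the 1 mm-isotropic test profile) on noiseless phantoms. Here the
lesion lies on the nipple axis, so the 2D projected distance nearly equals
the 3D one; off-axis lesions make `mip_2d` strictly smaller.

Cohort-level evaluation takes a CSV
(`patient_id, distance_auto_mm, distance_manual_mm, nac_involved`):

```sh
nac3d evaluate --cohort cohort.csv --cutoffs 5,10,20,30 --out report/
```

writing `metrics.csv` (one row per method × cut-off), `roc.csv`, and
`summary.json` with AUCs, best cut-offs and the DeLong p-value.

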