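"""Nipple-areola complex segmentation on the T2-weighted volume.

Step (a) of the distance pipeline: find the nipple as the most anterior
point of the body on the T2 MIP, grow the NAC by intensity region growing
(+/- 50% of the seed intensity by default), extract the posterior ("inner")
edge of the NAC mask, smooth it with a cubic B-spline and take the
arc-length midpoint of the curve as the single base-center point used for
the distance measurement.

Seeds are located on the axial maximum-intensity projection (with a depth
map to return to 3D), while region growing runs in 3D on the T2 volume: the
final base point must be a 3D world point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splrep
from skimage.filters import threshold_otsu

from .errors import DegenerateCurveError, DegenerateSeedError, SegmentationFailureError
from .image_io import ANATOMICAL_AXIS, BinaryMask3D, ImageVolume, canonicalize

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True, eq=False)
class NacSeed:
    """One seed voxel for NAC region growing."""

    index: tuple[int, int, int]
    world: np.ndarray
    intensity: float


@dataclass(frozen=True, eq=False)
class MipResult:
    """2D maximum-intensity projection plus per-pixel argmax depth."""

    image: np.ndarray
    depth: np.ndarray  # contributing slice index along the projection axis
    axis: int


@dataclass(frozen=True, eq=False)
class NacBaseModel:
    """Segmented NAC with its fitted base curve and base-center point."""

    nac_mask: BinaryMask3D
    base_curve: np.ndarray  # (n, 3) sampled world points
    control_points: np.ndarray  # (m, 3) raw boundary points the spline was fit to
    base_center_point: np.ndarray  # world mm, the distance endpoint
    qc_flags: frozenset[str] = frozenset()
    spline_tck: tuple = field(default=(), repr=False)

    @property
    def blocking_flags(self) -> frozenset[str]:
        return self.qc_flags & {"empty_mask", "base_curve_degenerate"}


def body_mask(t2: ImageVolume) -> BinaryMask3D:
    """Body extraction: Otsu threshold + largest 26-connected component +
    hole filling.  The minimal standard recipe; no claim beyond it."""
    t2 = canonicalize(t2)
    vox = np.asarray(t2.voxels, dtype=float)
    if vox.size == 0 or np.all(vox == vox.flat[0]):
        raise SegmentationFailureError("cannot threshold a constant volume")
    thr = threshold_otsu(vox)
    fg = vox > thr
    if not fg.any():
        raise SegmentationFailureError("body mask is empty after thresholding")
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return BinaryMask3D.like(t2, mask)


def compute_mip(volume: ImageVolume, axis="superior-inferior") -> MipResult:
    """Maximum-intensity projection along an anatomical axis.

    The depth map stores the (first) argmax slice index so a 2D detection
    can be mapped back into the 3D grid.
    """
    volume = canonicalize(volume)
    if volume.voxels.size == 0:
        raise ValueError("cannot project an empty volume")
    ax = ANATOMICAL_AXIS[axis] if isinstance(axis, str) else int(axis)
    vox = np.asarray(volume.voxels)
    return MipResult(image=vox.max(axis=ax), depth=vox.argmax(axis=ax), axis=ax)


def detect_nipple_seeds(
    t2: ImageVolume, body: BinaryMask3D, side: str = "both"
) -> dict[str, list[NacSeed]]:
    """Per breast, seed the nipple at the most anterior body voxel of that
    lateral half, plus its 8-connected axial in-plane neighbours.

    Ties on the anterior coordinate (flat surface) are broken toward the
    smallest index triple, deterministically, with a warning.
    """
    t2 = canonicalize(t2)
    if not body.voxels.any():
        raise SegmentationFailureError("body mask is empty")
    sides = ("left", "right") if side == "both" else (side,)
    mid = t2.shape[2] // 2
    out: dict[str, list[NacSeed]] = {}
    for s in sides:
        if s not in ("left", "right"):
            raise ValueError(f"side must be left/right/both, got {s!r}")
        half = np.zeros(t2.shape, dtype=bool)
        # axis 2 code is R: index increases toward the patient's right
        if s == "left":
            half[:, :, :mid] = True
        else:
            half[:, :, mid:] = True
        sub = body.voxels & half
        if not sub.any():
            raise SegmentationFailureError(f"body mask empty on {s} side")
        coords = np.argwhere(sub)
        j_max = coords[:, 1].max()
        apex_candidates = coords[coords[:, 1] == j_max]
        if len(apex_candidates) > 1:
            # flat anterior face at voxel resolution: take the candidate
            # nearest the centroid of the tie set (the geometric apex),
            # remaining ties toward the smallest index triple; deterministic
            warnings.warn(
                f"{len(apex_candidates)} equally anterior voxels on {s} side; "
                "tie broken toward the tie-set centroid",
                stacklevel=2,
            )
            centroid = apex_candidates.mean(axis=0)
            d2 = np.sum((apex_candidates - centroid) ** 2, axis=1)
            order = np.lexsort((apex_candidates[:, 2], apex_candidates[:, 1],
                                apex_candidates[:, 0], d2))
            apex_candidates = apex_candidates[order]
        apex = tuple(int(v) for v in apex_candidates[0])
        seeds = []
        i = apex[0]
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                j, k = apex[1] + dj, apex[2] + dk
                if not (0 <= j < t2.shape[1] and 0 <= k < t2.shape[2]):
                    continue
                if (dj, dk) != (0, 0) and not body.voxels[i, j, k]:
                    continue
                idx = (i, j, k)
                seeds.append(
                    NacSeed(idx, t2.index_to_world(np.array(idx, float)),
                            float(t2.voxels[idx]))
                )
        # apex first, then neighbours in deterministic scan order
        seeds.sort(key=lambda sd: (sd.index != apex, sd.index))
        out[s] = seeds
    return out


def grow_nac_region(
    t2: ImageVolume,
    seeds: list[NacSeed],
    tolerance_fraction: float = 0.5,
    body: BinaryMask3D | None = None,
) -> BinaryMask3D:
    """26-connected region growing from the seed group.

    A voxel v is admissible when ``|I(v) - m| <= tolerance_fraction * m``
    with m the mean intensity over the seed group; the result is the union
    of admissible components reachable from the seeds, equivalent to a
    breadth-first flood fill.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    if not (0 < tolerance_fraction <= 1):
        raise ValueError("tolerance_fraction must be in (0, 1]")
    t2 = canonicalize(t2)
    m = float(np.mean([s.intensity for s in seeds]))
    if m == 0:
        raise DegenerateSeedError("seed intensity is zero; relative tolerance undefined")
    admissible = np.abs(np.asarray(t2.voxels, dtype=float) - m) <= tolerance_fraction * abs(m)
    if body is not None:
        admissible &= body.voxels
    labels, _ = ndimage.label(admissible, structure=_STRUCT26)
    keep = {labels[s.index] for s in seeds if admissible[s.index]}
    keep.discard(0)
    mask = np.isin(labels, sorted(keep)) if keep else np.zeros(t2.shape, dtype=bool)
    return BinaryMask3D.like(t2, mask)


def fit_nac_base(
    nac_mask: BinaryMask3D,
    smoothing: float | None = None,
    n_samples: int = 512,
) -> NacBaseModel:
    """Fit the NAC base curve and pick its center point.

    The "inner edge" is taken per lateral column of the axially projected
    mask: the most posterior mask voxel of the column, lifted back to 3D at
    the mean superior position of those posterior voxels.  The ordered edge
    points are smoothed with a cubic B-spline (``splrep``; default smoothing
    factor = number of points, attenuating voxel-level irregularity) and the
    base-center point is the curve sample at the arc-length midpoint.
    """
    nac_mask = canonicalize(nac_mask)
    flags = set()
    vox = nac_mask.voxels
    if not vox.any():
        raise SegmentationFailureError("NAC mask is empty", qc_flags={"empty_mask"})
    border = (
        vox[0].any() or vox[-1].any()
        or vox[:, 0].any() or vox[:, -1].any()
        or vox[:, :, 0].any() or vox[:, :, -1].any()
    )
    if border:
        flags.add("mask_touches_image_border")

    proj = vox.any(axis=0)  # (j, k) axial projection
    ks = np.flatnonzero(proj.any(axis=0))
    pts = []
    for k in ks:
        j = int(np.flatnonzero(proj[:, k]).min())  # most posterior voxel of the column
        ii = np.flatnonzero(vox[:, j, k])
        pts.append((float(ii.mean()), float(j), float(k)))
    pts = np.asarray(pts, dtype=float)

    if len(pts) < 4:
        flags.add("base_curve_degenerate")
        raise DegenerateCurveError(
            f"only {len(pts)} base boundary points; need >= 4 for a cubic B-spline",
            qc_flags=flags,
        )

    world = nac_mask.index_to_world(pts)  # ordered along the lateral (x) arc
    x, y, z = world[:, 0], world[:, 1], world[:, 2]
    s = float(len(pts)) if smoothing is None else float(smoothing)
    tck_y = splrep(x, y, k=3, s=s)
    tck_z = splrep(x, z, k=3, s=s)
    xs = np.linspace(x[0], x[-1], n_samples)
    curve = np.stack([xs, splev(xs, tck_y), splev(xs, tck_z)], axis=1)

    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    half = arc[-1] / 2.0
    i = int(np.searchsorted(arc, half))
    if i == 0 or seg[i - 1] == 0:
        center = curve[i]
    else:  # interpolate within the segment for sub-sample placement
        t = (half - arc[i - 1]) / seg[i - 1]
        center = curve[i - 1] + t * (curve[i] - curve[i - 1])

    return NacBaseModel(
        nac_mask=nac_mask,
        base_curve=curve,
        control_points=world,
        base_center_point=center,
        qc_flags=frozenset(flags),
        spline_tck=(tck_y, tck_z),
    )


def segment_nac(
    t2: ImageVolume,
    side: str = "left",
    tolerance_fraction: float = 0.5,
    smoothing: float | None = None,
) -> NacBaseModel:
    """Convenience driver: body mask -> seeds -> region growing -> base fit."""
    t2 = canonicalize(t2)
    body = body_mask(t2)
    seeds = detect_nipple_seeds(t2, body, side=side)[side]
    mask = grow_nac_region(t2, seeds, tolerance_fraction=tolerance_fraction, body=body)
    return fit_nac_base(mask, smoothing=smoothing)
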