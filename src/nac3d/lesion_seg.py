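"""Enhancing-lesion segmentation on the DCE series.

Step (b) of the pipeline: segment the breast area on the pre-contrast
frame, normalise the series with the signal intensity of automatically
detected mammary vessels, threshold the relative-enhancement map, label the
connected components and filter out vessel-like and artefact-like false
positives.  The target lesion is then selected — by default the most
anterior candidate, the automated stand-in for the one manual step of the
clinical procedure.

Normalisation convention: both the pre and the chosen post frame are
divided by the vessel reference before computing

    RE(v) = (post(v) - pre(v)) / max(pre(v), eps)

which makes the thresholded map invariant to a global scanner gain (the
small-denominator floor eps scales with the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import LesionDetectionError, SegmentationFailureError
from .image_io import BinaryMask3D, DceSeries, ImageVolume, canonicalize

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionConfig:
    """Tunable thresholds of the lesion stage (reconstruction defaults)."""

    re_threshold: float = 0.5  # candidate iff RE >= this
    post_frame_index: int = 1  # second post-contrast frame
    min_volume_ml: float = 0.05  # below: speckle / artefact
    max_elongation: float = 5.0  # above: vessel-like
    exclude_border: bool = True  # candidates touching the grid border are artefacts
    vessel_re_threshold: float = 1.0
    vessel_min_elongation: float = 5.0
    vessel_max_volume_ml: float = 0.5
    chest_wall_area_fraction: float = 0.95


@dataclass(frozen=True, eq=False)
class LesionCandidate:
    """One 26-connected enhancing component with its shape descriptors."""

    mask: BinaryMask3D
    volume_ml: float
    centroid: np.ndarray  # world mm
    anterior_most_point: np.ndarray  # world mm
    elongation: float  # largest / smallest principal-axis length, >= 1
    touches_border: bool
    mean_relative_enhancement: float


@dataclass(frozen=True, eq=False)
class EnhancementMap:
    relative_enhancement: np.ndarray
    vessel_reference: float
    frame_index: int


def _relative_enhancement(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    tissue = pre[pre > 0]
    eps = max(1e-6, 1e-3 * float(np.median(tissue))) if tissue.size else 1e-6
    return (post - pre) / np.maximum(pre, eps)


def segment_breast(pre: ImageVolume, config: LesionConfig = LesionConfig()) -> BinaryMask3D:
    """Breast mask: body mask clipped anterior to the estimated chest wall.

    The chest-wall plane is taken where the per-slice body cross-section
    (area as a function of the anterior coordinate) last stays near its
    maximum: the chest has a large, roughly constant section while the
    breast mound tapers anteriorly.
    """
    pre = canonicalize(pre)
    vox = np.asarray(pre.voxels, dtype=float)
    if vox.size == 0 or np.all(vox == vox.flat[0]):
        raise SegmentationFailureError("cannot segment a constant volume")
    thr = threshold_otsu(vox)
    body = vox > thr
    if not body.any():
        raise SegmentationFailureError("body mask is empty")
    labels, n = ndimage.label(body, structure=_STRUCT26)
    largest = np.argmax(ndimage.sum_labels(body, labels, index=np.arange(1, n + 1))) + 1
    body = ndimage.binary_fill_holes(labels == largest)

    area = body.sum(axis=(0, 2))  # cross-section per anterior index j
    big = np.flatnonzero(area >= config.chest_wall_area_fraction * area.max())
    wall_j = int(big.max())
    mask = body.copy()
    mask[:, : wall_j + 1, :] = False
    return BinaryMask3D.like(pre, mask)


def _principal_lengths(coords_mm: np.ndarray, spacing) -> np.ndarray:
    """Principal-axis lengths from second moments of the voxel-center cloud,
    regularised by the single-voxel extent so a 1-voxel component is not
    degenerate."""
    cov = np.diag(np.asarray(spacing, dtype=float) ** 2 / 12.0)
    if len(coords_mm) > 1:
        cov = cov + np.cov(coords_mm.T)
    eig = np.clip(np.linalg.eigvalsh(cov), 1e-12, None)
    return np.sqrt(eig)


def _make_candidate(component: np.ndarray, geometry: ImageVolume, re_map: np.ndarray) -> LesionCandidate:
    idx = np.argwhere(component)
    world = geometry.index_to_world(idx.astype(float))
    # world axis 1 is anterior; ties fall to the smallest index triple
    # because argwhere scans in C order and argmax takes the first hit
    a = world[:, 1]
    anterior = world[int(np.argmax(a))]
    lengths = _principal_lengths(world, geometry.spacing)
    touches = bool(
        (idx == 0).any()
        or (idx[:, 0] == geometry.shape[0] - 1).any()
        or (idx[:, 1] == geometry.shape[1] - 1).any()
        or (idx[:, 2] == geometry.shape[2] - 1).any()
    )
    return LesionCandidate(
        mask=BinaryMask3D.like(geometry, component),
        volume_ml=float(len(idx) * np.prod(geometry.spacing) / 1000.0),
        centroid=world.mean(axis=0),
        anterior_most_point=anterior,
        elongation=float(lengths.max() / lengths.min()),
        touches_border=touches,
        mean_relative_enhancement=float(re_map[component].mean()),
    )


def vessel_reference(
    dce: DceSeries, breast: BinaryMask3D, config: LesionConfig = LesionConfig()
) -> tuple[float, BinaryMask3D]:
    """Mean post-contrast intensity over automatically detected vessels.

    Vessels are strongly enhancing (RE above ``vessel_re_threshold``),
    thin-elongated (elongation >= 5) and small (< 0.5 mL) components.  When
    none is found the 99.5th percentile of post-contrast intensity inside
    the breast is used instead, with a warning.
    """
    if not breast.voxels.any():
        raise SegmentationFailureError("breast mask is empty")
    pre = canonicalize(dce.pre)
    post = canonicalize(dce.post[min(config.post_frame_index, dce.n_post - 1)])
    re_map = _relative_enhancement(pre.voxels, post.voxels)
    cand = (re_map >= config.vessel_re_threshold) & breast.voxels
    labels, n = ndimage.label(cand, structure=_STRUCT26)
    vessel = np.zeros(pre.shape, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        c = _make_candidate(comp, pre, re_map)
        if c.elongation >= config.vessel_min_elongation and c.volume_ml < config.vessel_max_volume_ml:
            vessel |= comp
    if vessel.any():
        reference = float(np.asarray(post.voxels, dtype=float)[vessel].mean())
    else:
        warnings.warn(
            "no vessel candidate found; falling back to the 99.5th percentile "
            "of post-contrast breast intensity",
            stacklevel=2,
        )
        reference = float(np.percentile(np.asarray(post.voxels, dtype=float)[breast.voxels], 99.5))
    return reference, BinaryMask3D.like(pre, vessel)


def extract_enhancing_regions(
    dce: DceSeries,
    breast: BinaryMask3D,
    reference: float,
    config: LesionConfig = LesionConfig(),
) -> list[LesionCandidate]:
    """Threshold the vessel-normalised RE map and label candidates.

    Returns all 26-connected components with RE >= ``re_threshold`` inside
    the breast mask, most anterior first.  An empty list is the per-lesion
    miss case, not an error.
    """
    if reference <= 0:
        raise ValueError("vessel reference must be positive")
    pre = canonicalize(dce.pre)
    post = canonicalize(dce.post[min(config.post_frame_index, dce.n_post - 1)])
    re_map = _relative_enhancement(
        np.asarray(pre.voxels, dtype=float) / reference,
        np.asarray(post.voxels, dtype=float) / reference,
    )
    enhancing = (re_map >= config.re_threshold) & breast.voxels
    labels, n = ndimage.label(enhancing, structure=_STRUCT26)
    candidates = [_make_candidate(labels == lab, pre, re_map) for lab in range(1, n + 1)]
    candidates.sort(key=lambda c: -c.anterior_most_point[1])
    return candidates


def reduce_false_positives(
    candidates: list[LesionCandidate], config: LesionConfig = LesionConfig()
) -> list[LesionCandidate]:
    """Pure filter removing vessel-like, speckle and border-touching
    candidates; order preserved, idempotent, output is a subset of input."""
    kept = []
    for c in candidates:
        if c.volume_ml < config.min_volume_ml:
            continue
        if c.elongation > config.max_elongation:
            continue
        if config.exclude_border and c.touches_border:
            continue
        kept.append(c)
    return kept


def select_lesion(
    candidates: list[LesionCandidate], mode: str = "most_anterior", index: int | None = None
) -> LesionCandidate:
    """Pick the target lesion: the most anterior one (automated default for
    the procedure's single manual step) or an explicit index."""
    if not candidates:
        raise LesionDetectionError("no lesion candidate detected")
    if mode == "most_anterior":
        return max(candidates, key=lambda c: c.anterior_most_point[1])
    if mode == "by_index":
        if index is None or not (0 <= index < len(candidates)):
            raise IndexError(f"candidate index {index} out of range (0..{len(candidates) - 1})")
        return candidates[index]
    raise ValueError(f"unknown selection mode {mode!r}")


def segment_lesion(
    dce: DceSeries,
    config: LesionConfig = LesionConfig(),
    mode: str = "most_anterior",
    index: int | None = None,
) -> tuple[LesionCandidate, list[LesionCandidate]]:
    """Convenience driver: breast mask -> vessel reference -> candidates ->
    false-positive reduction -> selection.  Returns (selected, survivors)."""
    breast = segment_breast(dce.pre, config)
    reference, _ = vessel_reference(dce, breast, config)
    raw = extract_enhancing_regions(dce, breast, reference, config)
    kept = reduce_false_positives(raw, config)
    return select_lesion(kept, mode=mode, index=index), kept
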