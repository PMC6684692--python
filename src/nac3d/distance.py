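"""Tumour-to-NAC distance computation.

Step (c): the automated measurement is the 3D Euclidean distance in world
mm between the NAC base-center point and the closest lesion boundary-voxel
center.  The 2D variant emulates the manual caliper measurement on an axial
MIP by dropping the projection-axis coordinate from both endpoints before
minimising — which is why it can only ever under-estimate the 3D distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegmentationFailureError
from .lesion_seg import LesionCandidate
from .nipple_seg import NacBaseModel

#: cut-offs (mm) evaluated by default, the grid used in the literature
STANDARD_CUTOFFS_MM = (5.0, 10.0, 20.0, 21.0, 30.0)

_WORLD_AXIS_OF = {"superior-inferior": 2, "posterior-anterior": 1,
                  "anterior-posterior": 1, "left-right": 0}


@dataclass(frozen=True, eq=False)
class DistanceResult:
    distance_mm: float
    nac_point: np.ndarray  # world mm
    lesion_point: np.ndarray  # world mm (a lesion boundary voxel center)
    method: str  # auto_3d | mip_2d
    cutoff_calls: dict[float, bool] = field(default_factory=dict)


def boundary_voxels(mask) -> np.ndarray:
    """Indices (n, 3) of mask voxels with a 6-neighbour outside the mask."""
    vox = mask.voxels
    eroded = ndimage.binary_erosion(vox, structure=ndimage.generate_binary_structure(3, 1))
    return np.argwhere(vox & ~eroded)


def _check_inputs(nac: NacBaseModel, lesion: LesionCandidate):
    if nac.blocking_flags:
        raise SegmentationFailureError(
            f"NAC segmentation unusable (qc: {sorted(nac.blocking_flags)})",
            qc_flags=nac.blocking_flags,
        )
    if nac.qc_flags:
        warnings.warn(f"NAC qc flags present: {sorted(nac.qc_flags)}", stacklevel=3)
    if not lesion.mask.voxels.any():
        raise SegmentationFailureError("lesion mask is empty")


def _cutoff_calls(d: float) -> dict[float, bool]:
    return {c: bool(d <= c) for c in STANDARD_CUTOFFS_MM}


def distance_3d(nac: NacBaseModel, lesion: LesionCandidate) -> DistanceResult:
    """Minimum 3D Euclidean distance from the NAC base-center point to the
    lesion boundary, in world mm.

    The minimum is exhaustive over all boundary-voxel centers; exact ties
    resolve to the smallest voxel index triple.  A base point falling inside
    the lesion yields distance 0 with a warning.
    """
    _check_inputs(nac, lesion)
    base = np.asarray(nac.base_center_point, dtype=float)
    mask = lesion.mask

    idx = np.floor(mask.world_to_index(base) + 0.5).astype(int)
    if np.all((idx >= 0) & (idx < np.array(mask.shape))) and mask.voxels[tuple(idx)]:
        warnings.warn("NAC base point lies inside the lesion mask; distance clamped to 0",
                      stacklevel=2)
        point = mask.index_to_world(idx.astype(float))
        return DistanceResult(0.0, base, point, "auto_3d", _cutoff_calls(0.0))

    bnd = boundary_voxels(mask)  # argwhere C order: first minimum = smallest triple
    pts = mask.index_to_world(bnd.astype(float))
    dists = np.linalg.norm(pts - base, axis=1)
    i = int(np.argmin(dists))
    d = float(dists[i])
    return DistanceResult(d, base, pts[i], "auto_3d", _cutoff_calls(d))


def distance_2d_mip(
    nac: NacBaseModel, lesion: LesionCandidate, projection_axis: str = "superior-inferior"
) -> DistanceResult:
    """Projected (MIP-style) distance: both endpoints lose the projection-axis
    coordinate, then the 2D minimum over lesion boundary points is taken."""
    _check_inputs(nac, lesion)
    drop = _WORLD_AXIS_OF[projection_axis]
    keep = [a for a in range(3) if a != drop]
    base = np.asarray(nac.base_center_point, dtype=float)
    mask = lesion.mask

    idx = np.floor(mask.world_to_index(base) + 0.5).astype(int)
    if np.all((idx >= 0) & (idx < np.array(mask.shape))) and mask.voxels[tuple(idx)]:
        warnings.warn("NAC base point lies inside the lesion mask; distance clamped to 0",
                      stacklevel=2)
        point = mask.index_to_world(idx.astype(float))
        return DistanceResult(0.0, base, point, "mip_2d", _cutoff_calls(0.0))

    bnd = boundary_voxels(lesion.mask)
    pts = lesion.mask.index_to_world(bnd.astype(float))
    dists = np.linalg.norm(pts[:, keep] - base[keep], axis=1)
    i = int(np.argmin(dists))
    d = float(dists[i])
    return DistanceResult(d, base, pts[i], "mip_2d", _cutoff_calls(d))
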