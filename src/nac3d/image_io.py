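"""Volumetric containers and NIfTI / DICOM-series I/O.

All measurements downstream are made in world millimetres, so the only
geometric contract that matters is the voxel-to-world mapping.  The world
frame is RAS (+x toward patient right, +y anterior, +z superior).  Grid axes
are annotated with single-letter axis codes giving the anatomical direction
of *increasing* index (``R L A P S I``), the same convention nibabel uses
for its axcodes.

The canonical in-memory orientation is

* axis 0: superior -> inferior  (code ``I``)
* axis 1: posterior -> anterior (code ``A``)
* axis 2: left -> right         (code ``R``)

so that axial slices are ``volume.voxels[i]`` and "more anterior" always
means "larger index on axis 1".  T2 and DCE grids may differ (sagittal vs
axial, anisotropic vs isotropic); points from either are compared in mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError, OrientationError

#: direction of increasing index, per canonical axis
CANONICAL_AXCODES = ("I", "A", "R")

_WORLD_AXIS = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}
_SIGN = {"R": 1, "L": -1, "A": 1, "P": -1, "S": 1, "I": -1}

#: anatomical axis names accepted by projection/MIP helpers, mapped to the
#: canonical grid axis they correspond to.
ANATOMICAL_AXIS = {
    "superior-inferior": 0,
    "posterior-anterior": 1,
    "anterior-posterior": 1,
    "left-right": 2,
}


def _validate_geometry(voxels, spacing, origin, axcodes):
    if voxels.ndim != 3:
        raise GeometryError(f"expected a 3D grid, got ndim={voxels.ndim}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise GeometryError("spacing and origin must have 3 components")
    if any(s <= 0 for s in spacing):
        raise GeometryError(f"voxel spacing must be positive, got {spacing}")
    axcodes = tuple(axcodes)
    if sorted(_WORLD_AXIS.get(c, -1) for c in axcodes) != [0, 1, 2]:
        raise OrientationError(
            f"axis codes {axcodes} are not a bijection onto the anatomical axes"
        )
    return spacing, origin, axcodes


@dataclass(frozen=True, eq=False)
class ImageVolume:
    """3D scalar grid with an axis-aligned affine voxel-to-world mapping.

    ``origin`` is the world (RAS, mm) position of the *center* of voxel
    (0, 0, 0); voxel indices are 0-based.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axcodes: tuple[str, str, str] = CANONICAL_AXCODES

    def __post_init__(self):
        spacing, origin, axcodes = _validate_geometry(
            self.voxels, self.spacing, self.origin, self.axcodes
        )
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axcodes", axcodes)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (RAS mm) affine."""
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        for axis, code in enumerate(self.axcodes):
            w = _WORLD_AXIS[code]
            aff[w, axis] = _SIGN[code] * self.spacing[axis]
        aff[:3, 3] = self.origin
        return aff

    @property
    def anterior_axis(self) -> tuple[int, int]:
        """(grid axis, sign) such that moving by +sign steps goes anterior."""
        for axis, code in enumerate(self.axcodes):
            if _WORLD_AXIS[code] == 1:
                return axis, _SIGN[code]
        raise OrientationError("no anterior-posterior axis")  # pragma: no cover

    @property
    def is_canonical(self) -> bool:
        return self.axcodes == CANONICAL_AXCODES

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """Map voxel indices (..., 3) to world RAS mm (voxel centers)."""
        idx = np.asarray(index, dtype=float)
        world = np.empty(idx.shape, dtype=float)
        for axis, code in enumerate(self.axcodes):
            w = _WORLD_AXIS[code]
            world[..., w] = self.origin[w] + _SIGN[code] * self.spacing[axis] * idx[..., axis]
        return world

    def world_to_index(self, world) -> np.ndarray:
        """Inverse of :meth:`index_to_world` (continuous indices)."""
        pts = np.asarray(world, dtype=float)
        idx = np.empty(pts.shape, dtype=float)
        for axis, code in enumerate(self.axcodes):
            w = _WORLD_AXIS[code]
            idx[..., axis] = (pts[..., w] - self.origin[w]) / (_SIGN[code] * self.spacing[axis])
        return idx

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) over the grid."""
        coords = [None, None, None]
        for axis, code in enumerate(self.axcodes):
            w = _WORLD_AXIS[code]
            n = self.shape[axis]
            line = self.origin[w] + _SIGN[code] * self.spacing[axis] * np.arange(n)
            shape = [1, 1, 1]
            shape[axis] = n
            coords[w] = line.reshape(shape)
        return tuple(coords)

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.axcodes == other.axcodes
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return dataclasses.replace(self, voxels=voxels)


@dataclass(frozen=True, eq=False)
class BinaryMask3D(ImageVolume):
    """Boolean mask on the same grid as the volume it annotates."""

    def __post_init__(self):
        object.__setattr__(self, "voxels", np.asarray(self.voxels, dtype=bool))
        super().__post_init__()

    @classmethod
    def like(cls, volume: ImageVolume, voxels: np.ndarray) -> "BinaryMask3D":
        if voxels.shape != volume.shape:
            raise GeometryError("mask shape does not match its volume")
        return cls(np.asarray(voxels, dtype=bool), volume.spacing, volume.origin, volume.axcodes)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True, eq=False)
class DceSeries:
    """One pre-contrast frame plus >=1 post-contrast frames on one grid."""

    pre: ImageVolume
    post: tuple[ImageVolume, ...]
    temporal_resolution_s: float = 70.0

    def __post_init__(self):
        object.__setattr__(self, "post", tuple(self.post))
        if len(self.post) < 1:
            raise GeometryError("DCE series needs at least one post-contrast frame")
        if self.temporal_resolution_s <= 0:
            raise GeometryError("temporal resolution must be positive")
        for frame in self.post:
            if not self.pre.same_grid(frame):
                raise GeometryError("all DCE frames must share grid shape, spacing, origin")

    @property
    def n_post(self) -> int:
        return len(self.post)


# -- canonical orientation --------------------------------------------------


def canonicalize(volume: ImageVolume) -> ImageVolume:
    """Permute/flip grid axes to the canonical (I, A, R) orientation.

    The world coordinate of every voxel is unchanged; only the in-memory
    layout moves.  Applying it twice equals applying it once.
    """
    if volume.is_canonical:
        return volume
    perm = []
    flips = []
    for target in CANONICAL_AXCODES:
        want_world = _WORLD_AXIS[target]
        source = [a for a, c in enumerate(volume.axcodes) if _WORLD_AXIS[c] == want_world]
        if len(source) != 1:  # pragma: no cover - excluded by axcode validation
            raise OrientationError(f"cannot orient axes {volume.axcodes}")
        a = source[0]
        perm.append(a)
        flips.append(_SIGN[volume.axcodes[a]] != _SIGN[target])

    voxels = np.transpose(volume.voxels, perm)
    corner = np.zeros(3)  # source index of the voxel that becomes (0,0,0)
    for new_axis, (a, flip) in enumerate(zip(perm, flips)):
        if flip:
            voxels = np.flip(voxels, axis=new_axis)
            corner[a] = volume.shape[a] - 1
    origin = tuple(volume.index_to_world(corner))
    spacing = tuple(volume.spacing[a] for a in perm)
    cls = type(volume)
    return cls(np.ascontiguousarray(voxels), spacing, origin, CANONICAL_AXCODES)


# -- NIfTI ------------------------------------------------------------------


def _geometry_from_affine(affine: np.ndarray, path) -> tuple:
    rot = affine[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: zero-length voxel axis in affine")
    axcodes = []
    for axis in range(3):
        col = rot[:, axis]
        w = int(np.argmax(np.abs(col)))
        off = np.delete(np.abs(col), w)
        if np.any(off > 1e-3 * spacing[axis]):
            raise OrientationError(
                f"{path}: affine is not axis-aligned (oblique acquisitions unsupported)"
            )
        sign = 1 if col[w] > 0 else -1
        for code, waxis in _WORLD_AXIS.items():
            if waxis == w and _SIGN[code] == sign:
                axcodes.append(code)
                break
    return tuple(spacing), tuple(affine[:3, 3]), tuple(axcodes)


def read_volume(path, format: str | None = None, canonical: bool = True) -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an :class:`ImageVolume`.

    By default the result is brought to the canonical orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        vol = _read_nifti(path)
    elif format == "dicom_series":
        vol = _read_dicom_series(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return canonicalize(vol) if canonical else vol


def _read_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise FormatError(f"{path}: cannot parse NIfTI header ({exc})") from exc
    if affine is None:
        raise FormatError(f"{path}: NIfTI header has no affine")
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing, origin, axcodes = _geometry_from_affine(affine, path)
    return ImageVolume(data, spacing, origin, axcodes)


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI with its exact affine; read-back round-trips."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.voxels), volume.affine)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_mask(mask: BinaryMask3D, path) -> None:
    """Write a binary mask as a 0/1 uint8 NIfTI."""
    as_uint8 = ImageVolume(mask.voxels.astype(np.uint8), mask.spacing, mask.origin, mask.axcodes)
    write_volume(as_uint8, path)


def read_mask(path) -> BinaryMask3D:
    vol = read_volume(path)
    return BinaryMask3D(vol.voxels != 0, vol.spacing, vol.origin, vol.axcodes)


# -- DICOM series (read-only) ----------------------------------------------


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM clutter
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"{path}: no DICOM images found")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1 or None in uids:
        raise FormatError(f"{path}: slices do not share a single SeriesInstanceUID")
    for field in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        for ds in datasets:
            if getattr(ds, field, None) is None:
                raise FormatError(f"{path}: DICOM slice missing {field}")

    iop = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    row_vec, col_vec = iop[:3], iop[3:]  # along columns / along rows (LPS)
    normal = np.cross(row_vec, col_vec)
    positions = np.array([np.dot(normal, ds.ImagePositionPatient) for ds in datasets])
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = positions[order]

    if len(datasets) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise GeometryError(f"{path}: duplicate slice positions")
        if (steps.max() - steps.min()) > 1e-3 * steps.mean():
            raise GeometryError(
                f"{path}: inconsistent slice spacing (missing slice?): steps "
                f"{steps.min():.4g}..{steps.max():.4g} mm"
            )
        slice_spacing = float(steps.mean())
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    dr, dc = (float(v) for v in datasets[0].PixelSpacing)  # row, column spacing
    voxels = np.stack([ds.pixel_array for ds in datasets]).astype(np.float64)

    lps_to_ras = np.diag([-1.0, -1.0, 1.0])
    axis_vecs = [lps_to_ras @ normal, lps_to_ras @ col_vec, lps_to_ras @ row_vec]
    origin = lps_to_ras @ np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    spacing = (slice_spacing, dr, dc)

    axcodes = []
    for vec, sp in zip(axis_vecs, spacing):
        w = int(np.argmax(np.abs(vec)))
        if np.any(np.delete(np.abs(vec), w) > 1e-3):
            raise OrientationError(f"{path}: oblique DICOM series unsupported")
        sign = 1 if vec[w] > 0 else -1
        axcodes.append(next(c for c, wa in _WORLD_AXIS.items() if wa == w and _SIGN[c] == sign))
    return ImageVolume(voxels, spacing, tuple(origin), tuple(axcodes))


# -- cohort tables ----------------------------------------------------------

COHORT_COLUMNS = ("patient_id", "distance_auto_mm", "distance_manual_mm", "nac_involved")


def read_cohort_csv(path):
    """Read a cohort CSV into a DataFrame, dropping records without pathology.

    Accepts both ``distance_auto_mm`` and the legacy ``distance_mm_auto``
    spellings.  Records whose ``nac_involved`` label is missing are excluded
    (the reference standard was not specified for them).
    """
    import pandas as pd

    df = pd.read_csv(path)
    renames = {"distance_mm_auto": "distance_auto_mm", "distance_mm_manual": "distance_manual_mm"}
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    missing = [c for c in ("patient_id", "nac_involved") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort CSV missing columns {missing}")
    df = df[df["nac_involved"].notna()].copy()
    df["nac_involved"] = df["nac_involved"].astype(int).astype(bool)
    return df
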