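"""Synthetic breast phantoms with analytic ground truth.

The phantom emulates a prone breast acquisition: a posterior chest slab, a
half-ellipsoid breast mound, a protruding nipple with a bright areolar shell
(the NAC reads brighter than body tissue on T2, as it does clinically), a
spherical or ellipsoidal enhancing lesion inside the breast, and tubular
mammary vessels that enhance more strongly than the lesion.  The DCE series
is wash-in only: the pre-contrast frame carries no enhancement and every
post-contrast frame carries the full amplitude.

Ground truth is analytic: the NAC base-center point is the anterior apex of
the breast ellipsoid (where the nipple axis meets the mound), and the
tumour-to-NAC distance is the closed-form minimum distance from that point
to the lesion surface.

Two geometry profiles are provided.  ``PhantomSpec()`` is the fast test
profile (96 mm cube, 1 mm isotropic, axial DCE and axial T2 on the same
grid).  ``clinical_spec()`` mirrors a typical axial DCE acquisition
(0.7865 x 0.7865 mm in-plane, 3 mm slices) with a sagittal 3 mm T2, so the
two volumes really live on different grids and the world-mm contract is
exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import PhantomSpecError
from .image_io import BinaryMask3D, CANONICAL_AXCODES, DceSeries, ImageVolume

# baseline intensities (arbitrary units)
AIR = 0.0
BODY_T2 = 100.0
NAC_T2 = 300.0
TISSUE_PRE = 100.0


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: tuple[str, str, str] = CANONICAL_AXCODES

    def empty(self, fill=0.0, dtype=np.float64) -> ImageVolume:
        vox = np.full(self.shape, fill, dtype=dtype)
        return ImageVolume(vox, self.spacing_mm, self.origin, self.axcodes)


@dataclass(frozen=True)
class BreastSpec:
    """Half-ellipsoid breast mound anterior to the chest-wall plane."""

    center: tuple[float, float, float] = (47.5, 20.0, -47.5)  # on the chest wall
    radii: tuple[float, float, float] = (35.0, 45.0, 35.0)  # (x, y, z) mm


@dataclass(frozen=True)
class NippleSpec:
    """Protruding NAC bump: a half-ellipsoid sitting on the tangent plane at
    the breast apex (or at an explicit base-center point)."""

    height_mm: float = 7.0
    base_radius_mm: float = 8.0
    base_center: tuple[float, float, float] | None = None  # default: breast apex


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float, float] = (47.5, 40.0, -47.5)
    radii: tuple[float, float, float] = (6.0, 6.0, 6.0)
    amplitude: float = 1.5  # relative enhancement: post = pre * (1 + amplitude)


@dataclass(frozen=True)
class VesselSpec:
    p0: tuple[float, float, float] = (32.0, 55.0, -47.5)
    p1: tuple[float, float, float] = (63.0, 55.0, -47.5)
    radius_mm: float = 1.2
    amplitude: float = 3.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case; maps 1:1 to the YAML config."""

    grid: GridSpec = field(default_factory=GridSpec)
    t2_grid: GridSpec | None = None  # None -> same grid as DCE
    chest_wall_y: float = 20.0
    breast: BreastSpec = field(default_factory=BreastSpec)
    nipple: NippleSpec = field(default_factory=NippleSpec)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    vessels: tuple[VesselSpec, ...] = (VesselSpec(),)
    noise_sd: float = 0.0
    n_post_frames: int = 6
    temporal_resolution_s: float = 70.0
    rng_seed: int = 0

    @property
    def nipple_base_center(self) -> np.ndarray:
        """The NAC base-center point: the explicit nipple base-center if
        given, else the anterior apex of the breast ellipsoid."""
        if self.nipple.base_center is not None:
            return np.asarray(self.nipple.base_center, dtype=float)
        c = np.asarray(self.breast.center, dtype=float)
        return c + np.array([0.0, self.breast.radii[1], 0.0])

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if self.n_post_frames < 1:
            raise PhantomSpecError("need at least one post-contrast frame")
        c = np.asarray(self.breast.center, dtype=float)
        r = np.asarray(self.breast.radii, dtype=float)
        lc = np.asarray(self.lesion.center, dtype=float)
        lr = np.asarray(self.lesion.radii, dtype=float)
        # lesion surface sampled on a coarse sphere must stay inside the mound
        pts = lc + lr * _unit_sphere_samples(500)
        inside = np.sum(((pts - c) / r) ** 2, axis=1) <= 1.0
        anterior = pts[:, 1] >= self.chest_wall_y
        if not (np.all(inside) & np.all(anterior)):
            raise PhantomSpecError("lesion is not fully inside the breast")
        if analytic_truth_distance(self) <= 0:
            raise PhantomSpecError("lesion touches or contains the NAC base point")


def clinical_spec(**overrides) -> PhantomSpec:
    """Geometry profile mirroring an axial DCE / sagittal T2 acquisition."""
    dce = GridSpec(shape=(32, 122, 122), spacing_mm=(3.0, 0.7865, 0.7865))
    t2 = GridSpec(shape=(32, 113, 113), spacing_mm=(3.0, 0.8536, 0.8536),
                  axcodes=("R", "A", "I"), origin=(0.0, 0.0, 0.0))
    return PhantomSpec(grid=dce, t2_grid=t2, **overrides)


@dataclass(frozen=True)
class PhantomCase:
    t2: ImageVolume
    dce: DceSeries
    truth_nac_base_point: np.ndarray
    truth_lesion_mask: BinaryMask3D
    truth_distance_mm: float
    spec: PhantomSpec


# -- analytic ground truth --------------------------------------------------


def _unit_sphere_samples(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def point_to_ellipsoid_distance(point, center, radii) -> float:
    """Closed-form minimum distance from a point to an axis-aligned ellipsoid
    surface, clamped to 0 when the point is inside.

    Solves the Lagrange condition x_i = a_i^2 q_i / (a_i^2 + t) with
    sum (a_i q_i / (a_i^2 + t))^2 = 1 for the unique t > 0 (external point).
    """
    q = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    a = np.asarray(radii, dtype=float)
    if np.any(a <= 0):
        raise ValueError("ellipsoid radii must be positive")
    if np.sum((q / a) ** 2) <= 1.0:
        return 0.0
    if np.allclose(a, a[0]):  # sphere: trivial closed form
        return float(np.linalg.norm(q) - a[0])

    def f(t):
        return np.sum((a * q / (a**2 + t)) ** 2) - 1.0

    hi = np.linalg.norm(a * q)  # f(hi) <= 0 since a_i q_i/(a_i^2+hi) <= a_i q_i/hi
    t = brentq(f, 0.0, max(hi, 1e-12), xtol=1e-12, rtol=1e-15)
    x = a**2 * q / (a**2 + t)
    return float(np.linalg.norm(x - q))


def analytic_truth_distance(spec: PhantomSpec) -> float:
    """Closed-form tumour-to-NAC distance: NAC base point to lesion surface."""
    return point_to_ellipsoid_distance(
        spec.nipple_base_center, spec.lesion.center, spec.lesion.radii
    )


# -- rasterization ----------------------------------------------------------


def _memberships(grid: GridSpec, spec: PhantomSpec):
    """Boolean masks of every phantom structure on the given grid."""
    vol = grid.empty()
    x, y, z = vol.world_axes()
    c = spec.breast.center
    r = spec.breast.radii
    base = spec.nipple_base_center

    chest = y <= spec.chest_wall_y
    breast = (
        (((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0)
        & (y > spec.chest_wall_y)
    )
    lateral2 = (x - base[0]) ** 2 + (z - base[2]) ** 2
    nip = spec.nipple
    # the NAC bump: its posterior face is the base plane through base_center,
    # so the algorithm's "inner edge" and the analytic truth coincide
    nac = (
        lateral2 / nip.base_radius_mm**2 + ((y - base[1]) / nip.height_mm) ** 2 <= 1.0
    ) & (y >= base[1] - 1e-9)
    bump = nac

    lc, lr = spec.lesion.center, spec.lesion.radii
    lesion = (
        ((x - lc[0]) / lr[0]) ** 2 + ((y - lc[1]) / lr[1]) ** 2 + ((z - lc[2]) / lr[2]) ** 2
        <= 1.0
    )

    vessel = np.zeros(vol.shape, dtype=bool)
    for v in spec.vessels:
        vessel |= _tube_mask(x, y, z, v)

    body = chest | breast | bump
    return vol, body, breast | bump, nac, lesion & breast, vessel & body


def _tube_mask(x, y, z, v: VesselSpec) -> np.ndarray:
    p0 = np.asarray(v.p0, dtype=float)
    d = np.asarray(v.p1, dtype=float) - p0
    L2 = float(d @ d)
    px, py, pz = x - p0[0], y - p0[1], z - p0[2]
    t = np.clip((px * d[0] + py * d[1] + pz * d[2]) / L2, 0.0, 1.0)
    dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return dist2 <= v.radius_mm**2


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize a :class:`PhantomSpec` into T2 + DCE volumes with truth.

    Identical ``rng_seed`` gives bit-identical output; noise draws are made
    in a fixed order (T2, pre, post frames) from one generator.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    t2_grid = spec.t2_grid or spec.grid
    t2_vol, t2_body, _, t2_nac, _, _ = _memberships(t2_grid, spec)
    t2 = np.full(t2_vol.shape, AIR)
    t2[t2_body] = BODY_T2
    t2[t2_nac] = NAC_T2
    if spec.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, spec.noise_sd, size=t2.shape)
    t2_img = t2_vol.with_voxels(t2)

    dce_vol, body, _, _, lesion, vessel = _memberships(spec.grid, spec)
    pre = np.where(body, TISSUE_PRE, AIR)
    if spec.noise_sd > 0:
        pre_noisy = pre + rng.normal(0.0, spec.noise_sd, size=pre.shape)
    else:
        pre_noisy = pre
    pre_img = dce_vol.with_voxels(pre_noisy)

    gain = np.ones_like(pre)
    gain[lesion] = 1.0 + spec.lesion.amplitude
    gain[vessel] = 1.0 + max((v.amplitude for v in spec.vessels), default=0.0)
    posts = []
    for _ in range(spec.n_post_frames):
        frame = pre * gain
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        posts.append(dce_vol.with_voxels(frame))

    dce = DceSeries(pre_img, tuple(posts), spec.temporal_resolution_s)
    truth_mask = BinaryMask3D.like(dce_vol, lesion)
    return PhantomCase(
        t2=t2_img,
        dce=dce,
        truth_nac_base_point=spec.nipple_base_center,
        truth_lesion_mask=truth_mask,
        truth_distance_mm=analytic_truth_distance(spec),
        spec=spec,
    )


def sample_spec(rng_seed: int, noise_sd: float = 0.0, n_post_frames: int = 2) -> PhantomSpec:
    """Randomised-but-valid fast-profile phantom geometry for a given seed.

    Varies lesion position and size, nipple shape and vessel placement
    within bounds that keep the PhantomSpec invariants satisfied, so repeated
    seeds exercise different tumour-to-NAC distances and mask shapes.
    """
    rng = np.random.default_rng(rng_seed)
    lesion_center = (
        47.5 + rng.uniform(-6, 6),
        rng.uniform(32, 42),
        -47.5 + rng.uniform(-6, 6),
    )
    r = rng.uniform(5.0, 6.5)
    nipple = NippleSpec(
        height_mm=rng.uniform(6.0, 8.0), base_radius_mm=rng.uniform(7.0, 9.0)
    )
    vy = rng.uniform(53, 58)  # anterior of any lesion, never 26-adjacent to one
    vessel = VesselSpec(p0=(34.0, vy, -47.5), p1=(61.0, vy, -47.5))
    spec = PhantomSpec(
        lesion=LesionSpec(center=lesion_center, radii=(r, r, r)),
        nipple=nipple,
        vessels=(vessel,),
        noise_sd=noise_sd,
        n_post_frames=n_post_frames,
        rng_seed=int(rng_seed),
    )
    spec.validate()
    return spec


# -- config / disk round-trip ----------------------------------------------


def spec_to_dict(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["vessels"] = [asdict(v) for v in spec.vessels]
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    for key, cls in (("grid", GridSpec), ("breast", BreastSpec),
                     ("nipple", NippleSpec), ("lesion", LesionSpec)):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in d[key].items()})
    if d.get("t2_grid") is not None and isinstance(d["t2_grid"], dict):
        d["t2_grid"] = GridSpec(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in d["t2_grid"].items()})
    if "vessels" in d:
        d["vessels"] = tuple(
            VesselSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in vd.items()})
            for vd in d["vessels"]
        )
    return PhantomSpec(**d)


def load_spec(path) -> PhantomSpec:
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh) or {})


def write_phantom(case: PhantomCase, out_dir) -> dict:
    """Write t2/dce volumes, truth mask and truth.json; returns file map."""
    from . import image_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {"t2": out / "t2.nii.gz", "dce_pre": out / "dce_pre.nii.gz"}
    image_io.write_volume(case.t2, files["t2"])
    image_io.write_volume(case.dce.pre, files["dce_pre"])
    for i, frame in enumerate(case.dce.post, start=1):
        files[f"dce_post_{i}"] = out / f"dce_post_{i:02d}.nii.gz"
        image_io.write_volume(frame, files[f"dce_post_{i}"])
    files["lesion_mask"] = out / "lesion_mask.nii.gz"
    image_io.write_mask(case.truth_lesion_mask, files["lesion_mask"])
    truth = {
        "nac_base_point_mm": list(map(float, case.truth_nac_base_point)),
        "distance_mm": case.truth_distance_mm,
        "rng_seed": case.spec.rng_seed,
        "n_post_frames": case.spec.n_post_frames,
    }
    files["truth"] = out / "truth.json"
    files["truth"].write_text(json.dumps(truth, indent=2))
    return files
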