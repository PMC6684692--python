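import numpy as np
import pytest

from nac3d import ImageVolume, PhantomSpec, generate_phantom
from nac3d.image_io import _SIGN, _WORLD_AXIS, CANONICAL_AXCODES


@pytest.fixture(scope="session")
def default_case():
    """One noiseless fast-profile phantom shared by read-only tests."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def no_vessel_case():
    return generate_phantom(PhantomSpec(vessels=(), n_post_frames=2))


def reorient(volume: ImageVolume, new_axcodes) -> ImageVolume:
    """Re-express a volume under different axis codes without moving any
    voxel in world space (the inverse exercise of canonicalize)."""
    perm, flips = [], []
    for code in new_axcodes:
        src = next(a for a, c in enumerate(volume.axcodes)
                   if _WORLD_AXIS[c] == _WORLD_AXIS[code])
        perm.append(src)
        flips.append(_SIGN[volume.axcodes[src]] != _SIGN[code])
    vox = np.transpose(volume.voxels, perm)
    corner = np.zeros(3)
    for new_axis, (src, flip) in enumerate(zip(perm, flips)):
        if flip:
            vox = np.flip(vox, axis=new_axis)
            corner[src] = volume.shape[src] - 1
    origin = tuple(volume.index_to_world(corner))
    spacing = tuple(volume.spacing[a] for a in perm)
    return type(volume)(np.ascontiguousarray(vox), spacing, origin, tuple(new_axcodes))


def make_volume(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                axcodes=CANONICAL_AXCODES) -> ImageVolume:
    return ImageVolume(np.asarray(voxels, dtype=float), spacing, origin, axcodes)
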