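import numpy as np
import pytest

from deltarad import ContextMap, ImageVolume, NoduleMask


def disk_mask_3d(radius_px: int, n_slices: int = 3, spacing=(1.0, 1.0, 1.0)) -> NoduleMask:
    """Digital disk embedded in the middle axial slice of a thin volume."""
    n = 2 * radius_px + 21
    c = (n - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2
    vol = np.zeros((n, n, n_slices), dtype=bool)
    vol[:, :, n_slices // 2] = disk
    return NoduleMask(vol, spacing)


def sphere_mask(radius_mm: float, voxel_mm: float) -> NoduleMask:
    n = int(2 * radius_mm / voxel_mm) + 11
    c = (n - 1) / 2.0
    xx, yy, zz = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    r_vox = radius_mm / voxel_mm
    sph = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= r_vox**2
    return NoduleMask(sph, (voxel_mm,) * 3)


def lung_context_like(mask: NoduleMask) -> ContextMap:
    return ContextMap(np.zeros(mask.data.shape, dtype=np.int16), mask.spacing)


def constant_image_like(mask: NoduleMask, value: float) -> ImageVolume:
    return ImageVolume(np.full(mask.data.shape, value, dtype=float), mask.spacing)


@pytest.fixture(scope="session")
def small_phantom():
    from deltarad import PhantomSpec, generate_nodule_phantom

    return generate_nodule_phantom(
        PhantomSpec(diameter_mm=10.0, voxel_mm=0.5, sd_hu=60.0, spiculation_count=2), seed=11
    )
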