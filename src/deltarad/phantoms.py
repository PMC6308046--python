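"""Synthetic lung-nodule phantoms.

A phantom is a small CT-like volume containing one nodule: an ellipsoid of
configurable diameter, in-plane eccentricity and spatially correlated HU
texture, optionally decorated with cone-shaped spiculations and optionally
attached to a planar pleural wall.  Background mimics lung parenchyma
(about -800 HU).  Phantoms stand in for screening LDCT nodules so the whole
feature-extraction and modelling pipeline can be exercised end to end
without any patient data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import LUNG, PLEURAL_WALL, ContextMap, ImageVolume, NoduleMask

LUNG_HU = -800.0
LUNG_NOISE_SD = 50.0
WALL_HU = 40.0


@dataclass
class PhantomSpec:
    """Geometry and texture parameters of one synthetic nodule.

    Parameters
    ----------
    diameter_mm:
        In-plane longest diameter of the ellipsoid, mm.
    shape_eccentricity:
        In [0, 1); 0 gives a sphere, larger values shrink the minor axes to
        ``diameter * sqrt(1 - e^2)``.
    spiculation_count:
        Number of cone-shaped surface protrusions (length 0.3x radius).
    mean_hu, sd_hu:
        Mean and standard deviation of the in-nodule HU texture.
    texture_corr_len_mm:
        Correlation length of the Gaussian random field used as texture.
    pleural_attached:
        If true, a planar +40 HU wall is placed tangent to the nodule and
        labelled in the context map.
    voxel_mm:
        Isotropic voxel edge length.
    margin_mm:
        Clearance between the nodule surface and the volume faces; must be
        at least ``diameter_mm / 2``.
    """

    diameter_mm: float
    shape_eccentricity: float = 0.0
    spiculation_count: int = 0
    mean_hu: float = -40.0
    sd_hu: float = 80.0
    texture_corr_len_mm: float = 1.5
    pleural_attached: bool = False
    voxel_mm: float = 0.7
    margin_mm: float | None = None

    def __post_init__(self) -> None:
        if self.margin_mm is None:
            self.margin_mm = max(self.diameter_mm / 2.0, 3.0)
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if not (0.0 <= self.shape_eccentricity < 1.0):
            raise ValueError("shape_eccentricity must lie in [0, 1)")
        if self.spiculation_count < 0:
            raise ValueError("spiculation_count must be >= 0")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")
        if self.texture_corr_len_mm <= 0:
            raise ValueError("texture_corr_len_mm must be positive")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")
        if self.margin_mm < self.diameter_mm / 2.0:
            raise ValueError(
                "margin_mm must be at least diameter_mm / 2 "
                f"(got {self.margin_mm} < {self.diameter_mm / 2})"
            )


def _correlated_field(shape: tuple[int, ...], corr_len_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    sigma = max(corr_len_vox / 2.0, 1e-6)
    field = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def _largest_component(mask: np.ndarray) -> np.ndarray:
    # 6-connectivity; digitization can strand isolated spiculation voxels
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def generate_nodule_phantom(
    spec: PhantomSpec, seed: int, shape_seed: int | None = None
) -> tuple[ImageVolume, NoduleMask, ContextMap]:
    """Render one phantom nodule into a volume, mask and context map.

    Deterministic for a fixed ``(spec, seed)`` pair.  The mask is a single
    6-connected component and lies inside the volume with the margin given
    by ``spec.margin_mm``.  ``shape_seed`` (default: ``seed``) drives the geometry
    (spiculation orientations) separately from the HU texture, so a
    follow-up scan of the same nodule can rescale the shape while
    regenerating the texture.
    """
    rng = np.random.default_rng(seed)
    shape_rng = np.random.default_rng(seed if shape_seed is None else shape_seed)
    vx = spec.voxel_mm
    side_mm = spec.diameter_mm + 2.0 * spec.margin_mm
    n = int(np.ceil(side_mm / vx)) | 1  # odd so the centre falls on a voxel
    if n < 3:
        raise ValueError("volume too small for the requested nodule")
    shape = (n, n, n)
    centre = (np.array(shape) - 1) / 2.0

    a = spec.diameter_mm / 2.0 / vx  # semi-axis along x, voxels
    b = a * np.sqrt(1.0 - spec.shape_eccentricity**2)  # in-plane minor + z
    xx, yy, zz = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    dx, dy, dz = xx - centre[0], yy - centre[1], zz - centre[2]
    mask = (dx / a) ** 2 + (dy / b) ** 2 + (dz / b) ** 2 <= 1.0

    if spec.spiculation_count > 0:
        pts = np.stack([dx, dy, dz], axis=-1)
        length = 0.3 * a
        base_r = max(0.25 * a, 1.0)
        for _ in range(spec.spiculation_count):
            u = shape_rng.standard_normal(3)
            u[2] *= 0.25  # bias toward the axial plane so spiculations show in-slice
            u /= np.linalg.norm(u)
            # ellipsoid radius along u
            r_u = 1.0 / np.sqrt((u[0] / a) ** 2 + (u[1] / b) ** 2 + (u[2] / b) ** 2)
            t = pts @ u
            perp = np.linalg.norm(pts - t[..., None] * u, axis=-1)
            t0, t1 = 0.7 * r_u, r_u + length
            frac = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
            cone = (t >= t0) & (t <= t1) & (perp <= base_r * (1.0 - frac) + 0.3)
            mask |= cone

    mask = _largest_component(mask)
    if not mask.any():
        raise ValueError("volume too small: empty mask after rendering")

    image = LUNG_HU + LUNG_NOISE_SD * rng.standard_normal(shape)
    if spec.sd_hu > 0:
        texture = spec.mean_hu + spec.sd_hu * _correlated_field(
            shape, spec.texture_corr_len_mm / vx, rng
        )
    else:
        texture = np.full(shape, spec.mean_hu)
    image[mask] = texture[mask]

    context = np.full(shape, LUNG, dtype=np.int16)
    if spec.pleural_attached:
        # flatten the nodule slightly against the wall so the contact is a
        # face, not a single tangent voxel
        x_max = int(np.max(np.nonzero(mask.any(axis=(1, 2)))[0]))
        depth = max(1, int(round(0.1 * a)))
        wall_start = x_max + 1 - depth
        if wall_start >= n or wall_start < 1:
            raise ValueError("volume too small to place a tangent pleural wall")
        mask[wall_start:, :, :] = False
        mask = _largest_component(mask)
        if not mask.any():
            raise ValueError("volume too small: empty mask after wall placement")
        image[wall_start:, :, :] = WALL_HU + 10.0 * rng.standard_normal(
            image[wall_start:, :, :].shape
        )
        context[wall_start:, :, :] = PLEURAL_WALL

    spacing = (vx, vx, vx)
    return ImageVolume(image, spacing), NoduleMask(mask, spacing), ContextMap(context, spacing)
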