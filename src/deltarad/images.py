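"""In-memory containers for CT-like volumes, nodule masks and context labels.

Arrays are indexed ``(x, y, z)`` with the axial plane spanned by the first
two axes; ``spacing`` gives the voxel edge lengths in millimetres in the
same order.  Context maps label every voxel as lung parenchyma or pleural
wall so border-composition features can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: context-map label values
LUNG = 0
PLEURAL_WALL = 1


@dataclass
class ImageVolume:
    """A 3D grid of Hounsfield-unit values with isotropic-or-not voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class NoduleMask:
    """Binary segmentation of a single nodule."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class ContextMap:
    """Voxel labels for the tissue surrounding the nodule (lung vs pleural wall)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 3:
            raise ValueError("context map must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(obj: ImageVolume | NoduleMask | ContextMap, path: str | Path) -> None:
    """Write a volume/mask/context map as NIfTI, voxel spacing in the affine."""
    data = obj.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(obj.spacing))
    nib.save(img, str(path))


def load_nifti(path: str | Path, kind: str = "image") -> ImageVolume | NoduleMask | ContextMap:
    """Read a NIfTI file back into the requested container.

    ``kind`` is one of ``image``, ``mask``, ``context``.
    """
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj)
    if kind == "image":
        return ImageVolume(data, spacing)
    if kind == "mask":
        return NoduleMask(data > 0, spacing)
    if kind == "context":
        return ContextMap(data, spacing)
    raise ValueError(f"unknown kind {kind!r}")
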