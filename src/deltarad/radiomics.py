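"""Nodule feature extraction: size, shape, intensity, texture and pleural context.

Implements the named features consumed by the downstream delta-radiomics
models.  Conventions used throughout:

* 3D connectivity is 6-neighbour, 2D connectivity 4-neighbour;
* distances are between voxel centres, in millimetres via the spacing;
* the *representative slice* is the axial slice of maximal cross-sectional
  mask area (ties broken by the lowest slice index); 2D features are
  computed on it;
* intensity statistics use population (1/n) moments.

Definitions that have no single published formula (``MacSpic``,
``Asymmetry``, ``avgRLN``) follow the operationalisations documented with
each function; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from skimage import measure, morphology

from .images import PLEURAL_WALL, ContextMap, ImageVolume, NoduleMask

logger = logging.getLogger(__name__)

#: canonical ordered list of implemented feature names
FEATURE_CATALOG: tuple[str, ...] = (
    "Mean [HU]",
    "StdDev [HU]",
    "Number of pixels",
    "Volume (Pxl)",
    "Volume [cm]",
    "Longest diameter [mm]",
    "Short axis [mm]",
    "Short axis × Longest diameter",
    "Circularity",
    "Roundness",
    "Asymmetry",
    "MacSpic",
    "avgRLN",
    "Max dist COG to border [mm]",
    "SD dist COG to border [mm]",
    "Relative border to lung",
    "Relative border to pleural wall",
    "Is attached to pleural wall",
    "Laws L5 W5 L5",
    "Laws E5 E5 L5",
    "Laws E5 E5 R5",
    "3D Laws L5 W5 L5",
)

LAWS_VECTORS: dict[str, np.ndarray] = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}

#: the 13 unique 3D directions (26-neighbourhood modulo sign)
RUN_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def _check_pair(image: ImageVolume, mask: NoduleMask) -> None:
    if image.data.shape != mask.data.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.data.any():
        raise ValueError("empty mask")


def representative_slice_index(mask: NoduleMask) -> int:
    """Axial slice (last axis) with the largest mask area; lowest index wins ties."""
    if not mask.data.any():
        raise ValueError("empty mask")
    areas = mask.data.sum(axis=(0, 1))
    return int(np.argmax(areas))


# ---------------------------------------------------------------------------
# intensity and size


def intensity_and_size(image: ImageVolume, mask: NoduleMask) -> dict[str, float]:
    """Mean/SD HU, slice pixel count, voxel count and physical volume."""
    _check_pair(image, mask)
    values = image.data[mask.data]
    k = representative_slice_index(mask)
    voxel_vol = float(np.prod(mask.spacing))
    return {
        "Mean [HU]": float(values.mean()),
        "StdDev [HU]": float(values.std()),  # population SD
        "Number of pixels": float(mask.data[:, :, k].sum()),
        "Volume (Pxl)": float(mask.voxel_count),
        "Volume [cm]": float(mask.voxel_count * voxel_vol / 1000.0),
    }


# ---------------------------------------------------------------------------
# 2D shape on the representative slice


def _boundary_pixels_2d(slice_mask: np.ndarray) -> np.ndarray:
    """Indices (n, 2) of mask pixels with a 4-neighbour outside the mask."""
    eroded = ndimage.binary_erosion(
        slice_mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(slice_mask & ~eroded)


def _contour_perimeter_area(slice_mask: np.ndarray, sx: float, sy: float) -> tuple[float, float]:
    """Marching-squares outer contour of the mask: (perimeter mm, enclosed area mm2).

    The binary mask is lightly smoothed (sigma = 1 px) before contouring so
    the half-level contour tracks the physical boundary sub-pixel instead
    of the staircase; both statistics come from the same polygon, so the
    isoperimetric bound 4*pi*A <= P^2 holds by construction.
    """
    padded = np.pad(slice_mask.astype(float), 3)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    if smoothed.max() <= 0.5:  # structure too thin to survive smoothing
        smoothed = padded
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        return 0.0, 0.0
    c = max(contours, key=len) * np.array([sx, sy])
    seg = np.diff(c, axis=0)
    perimeter = float(np.sqrt((seg**2).sum(axis=1)).sum())
    x, y = c[:, 0], c[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return perimeter, area


def shape_metrics(mask: NoduleMask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Diameters, circularity, roundness, ellipse asymmetry and spiculation count.

    All quantities are measured on the representative axial slice.  MacSpic
    counts connected boundary protrusions that survive as residue after a
    morphological opening with a disk of radius ``longest diameter / 8``.
    """
    if spacing is None:
        spacing = mask.spacing
    sx, sy = float(spacing[0]), float(spacing[1])
    k = representative_slice_index(mask)
    sl = mask.data[:, :, k]

    boundary = _boundary_pixels_2d(sl)
    pts_mm = boundary * np.array([sx, sy])
    if len(pts_mm) == 1:
        ld = 0.0
        short_axis = 0.0
        direction = np.array([1.0, 0.0])
    else:
        dists = pdist(pts_mm)
        ld = float(dists.max())
        # recover the achieving pair to get the LD direction
        n_pts = len(pts_mm)
        idx = int(np.argmax(dists))
        i = int(n_pts - 2 - np.floor(np.sqrt(-8 * idx + 4 * n_pts * (n_pts - 1) - 7) / 2 - 0.5))
        j = int(idx + i + 1 - n_pts * (n_pts - 1) // 2 + (n_pts - i) * (n_pts - i - 1) // 2)
        direction = pts_mm[j] - pts_mm[i]
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0])
        perp = np.array([-direction[1], direction[0]])
        proj = pts_mm @ perp
        short_axis = float(proj.max() - proj.min())

    area_mm2 = float(sl.sum()) * sx * sy
    perim, area_poly = _contour_perimeter_area(sl, sx, sy)
    circularity = 4.0 * np.pi * area_poly / perim**2 if perim > 0 else 1.0
    # pixel area includes the half-pixel rim beyond boundary centres, so the
    # diameter it is compared against must too
    ld_ext = ld + (sx + sy) / 2.0
    roundness = 4.0 * area_mm2 / (np.pi * ld_ext**2) if ld > 0 else 1.0

    # best-fit ellipse from second moments of pixel centres (+ pixel self-moment)
    pix_mm = np.argwhere(sl) * np.array([sx, sy])
    centred = pix_mm - pix_mm.mean(axis=0)
    cov = centred.T @ centred / len(pix_mm)
    cov += np.diag([sx**2 / 12.0, sy**2 / 12.0])
    eigvals = np.sort(np.linalg.eigvalsh(cov))
    asymmetry = 1.0 - float(np.sqrt(max(eigvals[0], 0.0) / eigvals[1])) if eigvals[1] > 0 else 0.0

    macspic = _macspic(sl, ld, sx)

    return {
        "Longest diameter [mm]": ld,
        "Short axis [mm]": short_axis,
        "Short axis × Longest diameter": short_axis * ld,
        "Circularity": circularity,
        "Roundness": roundness,
        "Asymmetry": asymmetry,
        "MacSpic": float(macspic),
    }


def _macspic(slice_mask: np.ndarray, ld_mm: float, pixel_mm: float) -> int:
    """Count boundary protrusions: residue components of an opening with disk LD/8.

    Residue slivers thinner than 2 pixels are digitisation artefacts and are
    ignored, so a smooth disk scores 0.
    """
    radius_px = max(int(round(ld_mm / 8.0 / pixel_mm)), 1)
    opened = morphology.opening(slice_mask, morphology.disk(radius_px))
    residue = slice_mask & ~opened
    labels, n = ndimage.label(residue, structure=ndimage.generate_binary_structure(2, 1))
    if n == 0:
        return 0
    # components smaller than 4 px are digitisation slivers, not protrusions
    sizes = ndimage.sum_labels(residue, labels, index=np.arange(1, n + 1))
    return int((sizes >= 4).sum())


# ---------------------------------------------------------------------------
# Laws texture energies


def _laws_tokens(kernel_name: str) -> list[str]:
    tokens = kernel_name.replace("_", " ").split()
    if len(tokens) != 3 or any(t not in LAWS_VECTORS for t in tokens):
        raise ValueError(
            f"kernel name must be three tokens from {sorted(LAWS_VECTORS)}; got {kernel_name!r}"
        )
    return tokens


def _separable_response(image: np.ndarray, vectors: list[np.ndarray], axes: list[int]) -> np.ndarray:
    out = image
    for vec, ax in zip(vectors, axes):
        out = ndimage.correlate1d(out, vec, axis=ax, mode="nearest")
    return out


def laws_energy(
    image: ImageVolume, mask: NoduleMask, kernel_name: str, three_d: bool = False
) -> float:
    """Contrast-normalised Laws texture energy over the nodule.

    The kernel is the separable outer product of three 1D Laws vectors
    (L5 level, E5 edge, S5 spot, R5 ripple, W5 wave).  The statistic is the
    mean absolute filter response over in-mask voxels divided by the same
    statistic for the all-level (L5 L5 L5) kernel, which removes the HU
    scale.  The 2D variant applies the first two tokens in the axial plane
    per slice and averages over mask slices; the third token is ignored.
    """
    _check_pair(image, mask)
    tokens = _laws_tokens(kernel_name)
    if three_d:
        extent = [np.ptp(np.nonzero(mask.data.any(axis=tuple(a for a in range(3) if a != ax)))[0]) + 1
                  for ax in range(3)]
        if min(extent) < 5:
            raise ValueError("mask thinner than the 5-voxel kernel support")
        vecs = [LAWS_VECTORS[t] for t in tokens]
        num = np.abs(_separable_response(image.data, vecs, [0, 1, 2]))[mask.data].mean()
        den = np.abs(
            _separable_response(image.data, [LAWS_VECTORS["L5"]] * 3, [0, 1, 2])
        )[mask.data].mean()
    else:
        logger.debug("2D Laws kernel %s: third token %s ignored", kernel_name, tokens[2])
        vecs = [LAWS_VECTORS[t] for t in tokens[:2]]
        l5 = [LAWS_VECTORS["L5"]] * 2
        nums, dens = [], []
        for k in range(image.data.shape[2]):
            m = mask.data[:, :, k]
            if not m.any():
                continue
            sl = image.data[:, :, k]
            nums.append(np.abs(_separable_response(sl, vecs, [0, 1]))[m].mean())
            dens.append(np.abs(_separable_response(sl, l5, [0, 1]))[m].mean())
        num, den = float(np.mean(nums)), float(np.mean(dens))
    if den == 0.0:
        logger.warning("zero L5 normaliser (zero-HU constant image); returning 0")
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------------
# grey-level run-length


def _quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.int32)
    levels = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int32)
    return np.clip(levels, 0, n_levels - 1)


def run_length_avgRLN(image: ImageVolume, mask: NoduleMask, n_gray_levels: int = 16) -> float:
    """Run-length nonuniformity averaged over the 13 unique 3D directions.

    In-mask HU values are quantised uniformly between their min and max into
    ``n_gray_levels`` bins.  For each direction the grey-level run-length
    matrix p(i, j) is built from maximal same-level runs of in-mask voxels;
    RLN = sum_j (sum_i p(i,j))^2 / sum p, favouring few long runs.
    """
    _check_pair(image, mask)
    # crop to the mask bounding box for speed
    idx = np.nonzero(mask.data)
    lo = [int(v.min()) for v in idx]
    hi = [int(v.max()) + 1 for v in idx]
    sub_mask = mask.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub_img = image.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    levels = np.full(sub_mask.shape, -1, dtype=np.int32)
    levels[sub_mask] = _quantize(sub_img[sub_mask], n_gray_levels)

    rlns = [_direction_rln(levels, d) for d in RUN_DIRECTIONS]
    return float(np.mean([r for r in rlns if r is not None]))


def _direction_rln(levels: np.ndarray, d: tuple[int, int, int]) -> float | None:
    """RLN for one direction; ``levels`` holds grey levels with -1 outside the mask."""
    shape = np.array(levels.shape)
    dvec = np.array(d)
    grid = np.indices(levels.shape)
    prev = grid - dvec.reshape(3, 1, 1, 1)
    outside_prev = ((prev < 0) | (prev >= shape.reshape(3, 1, 1, 1))).any(axis=0)
    starts = np.argwhere(outside_prev)  # one line per entry voxel
    t_max = int(shape.max())
    t = np.arange(t_max)
    pos = starts[:, None, :] + t[None, :, None] * dvec  # (lines, t, 3)
    valid = ((pos >= 0) & (pos < shape)).all(axis=2)
    posc = np.clip(pos, 0, shape - 1)
    lines = levels[posc[..., 0], posc[..., 1], posc[..., 2]]
    lines[~valid] = -1
    # flatten lines with -1 separators so runs never span rows
    sep = np.full((lines.shape[0], 1), -1, dtype=lines.dtype)
    flat = np.concatenate([lines, sep], axis=1).ravel()
    in_run = flat >= 0
    change = np.empty(len(flat), dtype=bool)
    change[0] = True
    change[1:] = flat[1:] != flat[:-1]
    run_starts = np.nonzero(in_run & change)[0]
    end_mark = in_run.copy()
    end_mark[:-1] &= flat[1:] != flat[:-1]
    run_ends = np.nonzero(end_mark)[0]
    if len(run_starts) == 0:
        return None
    lengths = run_ends - run_starts + 1
    counts = np.bincount(lengths)
    total = counts.sum()
    return float((counts.astype(np.float64) ** 2).sum() / total)


# ---------------------------------------------------------------------------
# centroid-to-border distances and pleural context


def cog_border_and_context(
    mask: NoduleMask, context: ContextMap, spacing: tuple[float, float, float] | None = None
) -> dict[str, float]:
    """Distances from the centroid to the border, and border tissue composition.

    Boundary voxels are in-mask voxels with at least one 6-neighbour outside
    the mask; the fraction of boundary voxels whose outside neighbours
    include a pleural-wall voxel gives the relative wall border.
    """
    if context.data.shape != mask.data.shape:
        raise ValueError("context map does not cover the mask volume")
    if not mask.data.any():
        raise ValueError("empty mask")
    if spacing is None:
        spacing = mask.spacing
    sp = np.asarray(spacing, dtype=float)

    m = mask.data
    coords = np.argwhere(m)
    cog = coords.mean(axis=0)

    wall = context.data == PLEURAL_WALL
    shape = np.array(m.shape)
    is_boundary = np.zeros(len(coords), dtype=bool)
    touches_wall = np.zeros(len(coords), dtype=bool)
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        nb = coords + np.array(d)
        inside = ((nb >= 0) & (nb < shape)).all(axis=1)
        out_of_mask = ~inside.copy()
        wall_nb = np.zeros(len(coords), dtype=bool)
        if inside.any():
            vals = m[tuple(nb[inside].T)]
            out_of_mask[inside] = ~vals
            wall_vals = wall[tuple(nb[inside].T)]
            wall_nb[inside] = wall_vals & ~vals
        is_boundary |= out_of_mask
        touches_wall |= wall_nb
    bcoords = coords[is_boundary]
    dists = np.sqrt((((bcoords - cog) * sp) ** 2).sum(axis=1))
    n_b = len(bcoords)
    rel_wall = float(touches_wall[is_boundary].sum() / n_b) if n_b else 0.0
    return {
        "Max dist COG to border [mm]": float(dists.max()) if n_b else 0.0,
        "SD dist COG to border [mm]": float(dists.std()) if n_b else 0.0,
        "Relative border to lung": 1.0 - rel_wall,
        "Relative border to pleural wall": rel_wall,
        "Is attached to pleural wall": 1.0 if rel_wall > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# full vector


def extract_all_features(
    image: ImageVolume, mask: NoduleMask, context: ContextMap
) -> dict[str, float]:
    """Compute every catalogued feature; returns a name -> value map in catalog order."""
    out: dict[str, float] = {}
    out.update(intensity_and_size(image, mask))
    out.update(shape_metrics(mask))
    out["avgRLN"] = run_length_avgRLN(image, mask)
    out.update(cog_border_and_context(mask, context))
    out["Laws L5 W5 L5"] = laws_energy(image, mask, "L5 W5 L5")
    out["Laws E5 E5 L5"] = laws_energy(image, mask, "E5 E5 L5")
    out["Laws E5 E5 R5"] = laws_energy(image, mask, "E5 E5 R5")
    try:
        out["3D Laws L5 W5 L5"] = laws_energy(image, mask, "L5 W5 L5", three_d=True)
    except ValueError:
        # mask thinner than the 3D kernel support: fall back to the planar value
        out["3D Laws L5 W5 L5"] = out["Laws L5 W5 L5"]
    return {name: out[name] for name in FEATURE_CATALOG}
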