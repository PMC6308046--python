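"""Size, shape, intensity and pleural-context features on analytic phantoms."""

import numpy as np
import pytest

from deltarad import (
    ContextMap,
    ImageVolume,
    NoduleMask,
    cog_border_and_context,
    extract_all_features,
    intensity_and_size,
    shape_metrics,
)
from deltarad.images import PLEURAL_WALL
from deltarad.radiomics import FEATURE_CATALOG

from conftest import constant_image_like, disk_mask_3d, lung_context_like, sphere_mask


class TestIntensityAndSize:
    def test_constant_image(self):
        mask = disk_mask_3d(6)
        out = intensity_and_size(constant_image_like(mask, -37.5), mask)
        assert out["Mean [HU]"] == -37.5
        assert out["StdDev [HU]"] == 0.0

    def test_sphere_volume_cm3(self):
        mask = sphere_mask(5.0, 0.5)
        img = constant_image_like(mask, 0.0)
        out = intensity_and_size(img, mask)
        assert abs(out["Volume [cm]"] - 0.5236) / 0.5236 < 0.05

    def test_single_voxel(self):
        vol = np.zeros((5, 5, 5), bool)
        vol[2, 2, 2] = True
        mask = NoduleMask(vol, (1.0, 1.0, 1.0))
        out = intensity_and_size(constant_image_like(mask, 1.0), mask)
        assert out["Volume (Pxl)"] == 1
        assert out["Volume [cm]"] == pytest.approx(0.001)
        assert out["Number of pixels"] == 1

    def test_slice_pixels_vs_total_voxels(self):
        mask = sphere_mask(5.0, 0.5)
        out = intensity_and_size(constant_image_like(mask, 0.0), mask)
        assert out["Number of pixels"] < out["Volume (Pxl)"]

    def test_empty_mask_raises(self):
        mask = NoduleMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            intensity_and_size(constant_image_like(mask, 0.0), mask)

    def test_shape_mismatch_raises(self):
        mask = disk_mask_3d(4)
        img = ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError):
            intensity_and_size(img, mask)


class TestShapeMetrics:
    def test_fine_disk_is_round(self):
        out = shape_metrics(disk_mask_3d(50))
        assert 0.95 <= out["Circularity"] <= 1.0
        assert 0.95 <= out["Roundness"] <= 1.0
        assert out["Asymmetry"] < 0.05
        assert out["MacSpic"] == 0

    def test_square_circularity_approaches_pi_over_4(self):
        n, s = 120, 100
        vol = np.zeros((n, n, 3), bool)
        vol[10:10 + s, 10:10 + s, 1] = True
        out = shape_metrics(NoduleMask(vol, (1, 1, 1)))
        assert abs(out["Circularity"] - np.pi / 4) < 0.03

    def test_two_to_one_ellipse_asymmetry(self):
        n = 131
        c = (n - 1) / 2
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        vol = np.zeros((n, n, 3), bool)
        vol[:, :, 1] = (xx - c) ** 2 / 50**2 + (yy - c) ** 2 / 25**2 <= 1.0
        out = shape_metrics(NoduleMask(vol, (1, 1, 1)))
        assert abs(out["Asymmetry"] - 0.5) < 0.05

    def test_diameters_on_disk(self):
        out = shape_metrics(disk_mask_3d(25))
        assert out["Longest diameter [mm]"] == pytest.approx(50.0, abs=1.0)
        assert out["Short axis [mm]"] == pytest.approx(50.0, abs=1.5)
        assert out["Short axis × Longest diameter"] == pytest.approx(
            out["Short axis [mm]"] * out["Longest diameter [mm]"]
        )

    def test_upscaling_monotonicity(self):
        small = shape_metrics(disk_mask_3d(15))
        big = shape_metrics(disk_mask_3d(30))
        assert big["Longest diameter [mm]"] > small["Longest diameter [mm]"]


class TestCogBorderAndContext:
    def test_isolated_sphere(self):
        mask = sphere_mask(5.0, 0.5)
        out = cog_border_and_context(mask, lung_context_like(mask))
        assert abs(out["Max dist COG to border [mm]"] - 5.0) <= 0.5
        assert out["SD dist COG to border [mm]"] < 0.2 * 5.0
        assert out["Relative border to lung"] == 1.0
        assert out["Is attached to pleural wall"] == 0.0

    def test_hemisphere_flush_on_wall(self):
        # digital hemisphere: flat face against a wall slab
        full = sphere_mask(8.0, 0.5)
        cut = full.data.copy()
        c = (cut.shape[0] - 1) // 2
        cut[c + 1:, :, :] = False
        mask = NoduleMask(cut, full.spacing)
        ctx = np.zeros(cut.shape, dtype=np.int16)
        ctx[c + 1:, :, :] = PLEURAL_WALL
        out = cog_border_and_context(mask, ContextMap(ctx, full.spacing))
        assert out["Is attached to pleural wall"] == 1.0
        # analytic share of the flat face among boundary voxels of the phantom
        flat = int((mask.data[c] & ~np.zeros_like(mask.data[c])).sum())
        boundary_total = _count_boundary(mask.data)
        assert abs(out["Relative border to pleural wall"] - flat / boundary_total) < 0.1

    def test_single_voxel(self):
        vol = np.zeros((5, 5, 5), bool)
        vol[2, 2, 2] = True
        mask = NoduleMask(vol, (1, 1, 1))
        out = cog_border_and_context(mask, lung_context_like(mask))
        assert out["Max dist COG to border [mm]"] == 0.0
        assert out["SD dist COG to border [mm]"] == 0.0

    def test_context_shape_mismatch_raises(self):
        mask = disk_mask_3d(4)
        with pytest.raises(ValueError):
            cog_border_and_context(mask, ContextMap(np.zeros((2, 2, 2)), mask.spacing))


def _count_boundary(m):
    from scipy import ndimage

    eroded = ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1), border_value=0)
    return int((m & ~eroded).sum())


class TestExtractAll:
    def test_complete_and_finite(self, small_phantom):
        img, mask, ctx = small_phantom
        fv = extract_all_features(img, mask, ctx)
        assert list(fv) == list(FEATURE_CATALOG)
        assert all(np.isfinite(v) for v in fv.values())

    def test_deterministic(self, small_phantom):
        img, mask, ctx = small_phantom
        assert extract_all_features(img, mask, ctx) == extract_all_features(img, mask, ctx)

    def test_translation_invariance(self, small_phantom):
        img, mask, ctx = small_phantom
        shift = (2, -1, 1)
        img2 = ImageVolume(np.roll(img.data, shift, (0, 1, 2)), img.spacing)
        mask2 = NoduleMask(np.roll(mask.data, shift, (0, 1, 2)), mask.spacing)
        ctx2 = ContextMap(np.roll(ctx.data, shift, (0, 1, 2)), ctx.spacing)
        a = extract_all_features(img, mask, ctx)
        b = extract_all_features(img2, mask2, ctx2)
        for name in FEATURE_CATALOG:
            if "border" in name.lower() or "attached" in name.lower():
                continue
            assert a[name] == pytest.approx(b[name], abs=1e-6), name

    def test_dimensionless_ranges(self, small_phantom):
        img, mask, ctx = small_phantom
        fv = extract_all_features(img, mask, ctx)
        for name in ("Circularity", "Roundness", "Asymmetry",
                     "Relative border to lung", "Relative border to pleural wall"):
            assert 0.0 <= fv[name] <= 1.05, name
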