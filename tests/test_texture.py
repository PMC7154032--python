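"""Heterogeneity metrics, Tamura features, segmentation and partition.

The Tamura features are checked against independent naive (double-loop)
reimplementations of the same documented definitions (see _oracles.py).
"""

import numpy as np
import pytest

from msom.recon import Volume
from _oracles import checkerboard, naive_coarseness, naive_contrast, naive_directionality
from msom.texture import (
    histogram_metrics,
    partition_centre_rim,
    relative_difference,
    segment_tumour,
    tamura_coarseness,
    tamura_contrast,
    tamura_directionality,
    whole_tumour_metrics,
)


# ---------------------------------------------------------------------------
# histogram statistics
# ---------------------------------------------------------------------------

class TestHistogramMetrics:
    def test_constant_image(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = histogram_metrics(np.full((16, 16), 2.5))
        assert m["variance"] == 0.0
        assert m["energy"] == 1.0
        assert m["entropy"] == 0.0
        assert np.isnan(m["skewness"]) and np.isnan(m["kurtosis"])

    def test_symmetric_two_point_distribution(self):
        a, b = 1.0, 5.0
        img = np.array([[a] * 8 + [b] * 8] * 4)
        m = histogram_metrics(img)
        assert m["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert m["entropy"] == pytest.approx(1.0, abs=1e-12)  # one bit
        assert m["variance"] == pytest.approx(((b - a) / 2) ** 2, rel=1e-12)

    def test_gaussian_samples_closed_form(self):
        x = np.random.default_rng(1).normal(size=10 ** 6).reshape(1000, 1000)
        m = histogram_metrics(x)
        assert m["skewness"] == pytest.approx(0.0, abs=0.01)
        assert m["kurtosis"] == pytest.approx(3.0, abs=0.02)

    def test_pixel_order_invariance(self, rng):
        img = rng.random((20, 20))
        shuffled = rng.permutation(img.ravel()).reshape(20, 20)
        assert histogram_metrics(img) == histogram_metrics(shuffled)

    def test_affine_map_behaviour(self, rng):
        img = rng.random((32, 32))
        m = histogram_metrics(img)
        m2 = histogram_metrics(3.0 * img + 2.0)
        assert m2["mean"] == pytest.approx(3.0 * m["mean"] + 2.0, rel=1e-9)
        assert m2["variance"] == pytest.approx(9.0 * m["variance"], rel=1e-9)
        for key in ("skewness", "kurtosis", "energy", "entropy"):
            assert m2[key] == pytest.approx(m[key], rel=1e-9)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            histogram_metrics(rng.random((4, 4)), np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# Tamura features
# ---------------------------------------------------------------------------

class TestTamura:
    def test_coarseness_matches_naive_oracle_exactly(self, rng):
        for _ in range(5):
            img = rng.random((16, 16))
            assert tamura_coarseness(img) == naive_coarseness(img)

    def test_coarseness_monotone_in_tile_size(self):
        assert tamura_coarseness(checkerboard(2)) < tamura_coarseness(
            checkerboard(16))

    def test_constant_image_coarseness_two(self):
        assert tamura_coarseness(np.ones((64, 64))) == 2.0

    def test_coarseness_offset_invariant(self, rng):
        img = rng.random((32, 32))
        assert tamura_coarseness(img + 7.0) == pytest.approx(
            tamura_coarseness(img), rel=1e-12)

    def test_contrast_matches_naive_oracle_exactly(self, rng):
        for _ in range(5):
            img = rng.random((16, 16))
            assert tamura_contrast(img) == pytest.approx(naive_contrast(img),
                                                         rel=1e-12)

    def test_contrast_binary_image_is_one(self):
        img = np.ones((32, 32))
        img[:, :16] = -1.0
        assert tamura_contrast(img) == pytest.approx(1.0, rel=1e-12)

    def test_contrast_constant_zero_and_scaling(self, rng):
        assert tamura_contrast(np.full((8, 8), 4.0)) == 0.0
        img = rng.random((16, 16))
        assert tamura_contrast(2.5 * img) == pytest.approx(
            2.5 * tamura_contrast(img), rel=1e-9)

    def test_directionality_matches_naive_oracle_exactly(self, rng):
        for _ in range(5):
            img = rng.random((16, 16))
            got = tamura_directionality(img)
            want = naive_directionality(img)
            assert got == pytest.approx(want, abs=1e-12)

    def test_directionality_stripes_high(self):
        stripes = np.tile(np.arange(64) % 2, (64, 1)).astype(float)
        assert tamura_directionality(stripes) > 0.9

    def test_directionality_noise_below_stripes(self, rng):
        stripes = np.tile(np.arange(64) % 2, (64, 1)).astype(float)
        noise = rng.normal(size=(128, 128))
        assert tamura_directionality(noise) < tamura_directionality(stripes)

    def test_directionality_rotation_invariant(self):
        stripes = np.tile(np.sin(np.arange(64) * 0.7), (64, 1))
        d0 = tamura_directionality(stripes)
        d90 = tamura_directionality(np.rot90(stripes).copy())
        assert d90 == pytest.approx(d0, rel=0.02)


# ---------------------------------------------------------------------------
# segmentation and partition
# ---------------------------------------------------------------------------

def disc_image(radius=40, n=128, centre=(64, 64)):
    yy, xx = np.mgrid[:n, :n]
    return (((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2)
            <= radius ** 2).astype(float)


class TestSegmentation:
    def test_disc_mask_area(self):
        img = disc_image()
        seg = segment_tumour(img)
        true_area = img.sum()
        assert abs(seg.mask.sum() - true_area) / true_area <= 0.02

    def test_all_zero_image_fails(self):
        with pytest.raises(ValueError, match="segmentation failed"):
            segment_tumour(np.zeros((64, 64)))

    def test_speck_excluded_by_largest_component(self):
        img = disc_image()
        img[5:8, 5:8] = 1.0
        seg = segment_tumour(img)
        assert not seg.mask[6, 6]


class TestPartition:
    def test_disc_cutoff_half_area_ratio(self):
        seg = segment_tumour(disc_image())
        centre, rim = partition_centre_rim(seg, cutoff_fraction=0.5)
        ratio = centre.mask.sum() / seg.mask.sum()
        assert ratio == pytest.approx(0.25, abs=0.02)

    def test_cutoff_limits(self):
        seg = segment_tumour(disc_image())
        c_hi, r_hi = partition_centre_rim(seg, cutoff_fraction=0.99)
        c_lo, r_lo = partition_centre_rim(seg, cutoff_fraction=0.01)
        assert r_hi.mask.sum() < 0.1 * seg.mask.sum()
        assert c_lo.mask.sum() < 0.1 * seg.mask.sum()

    def test_star_convex_partition_exact(self, rng):
        # star-convex blob: radius varies smoothly with angle
        n = 96
        yy, xx = np.mgrid[:n, :n]
        ang = np.arctan2(yy - 48, xx - 48)
        radius = 25 + 10 * np.sin(3 * ang)
        mask = np.hypot(yy - 48, xx - 48) <= radius
        from msom.texture import RegionMask
        region = RegionMask(mask, "whole", (48.0, 48.0))
        centre, rim = partition_centre_rim(region, cutoff_fraction=0.6)
        assert np.array_equal(centre.mask | rim.mask, mask)
        assert not np.any(centre.mask & rim.mask)

    def test_centre_outside_mask_rejected(self):
        from msom.texture import RegionMask
        mask = disc_image().astype(bool)
        with pytest.raises(ValueError, match="outside"):
            partition_centre_rim(RegionMask(mask, "whole", (2.0, 2.0)), 0.5)


class TestRelativeDifference:
    @pytest.mark.parametrize("c, r, expected", [
        (5.0, 5.0, 0.0),
        (3.0, 1.0, 0.5),
        (4.0, 0.0, 1.0),
    ])
    def test_closed_forms(self, c, r, expected):
        assert relative_difference(c, r) == expected

    def test_zero_sum_masked(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(relative_difference(0.0, 0.0))


class TestWholeTumourMetrics:
    @staticmethod
    def _rim_core_volume(n=64, voxel=50.0):
        """Bright rim shell, dim core, zero background; identical z-slices."""
        half = (n - 1) / 2.0
        coords = (np.arange(n) - half) * voxel
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        r = np.hypot(yy, xx)
        sl = np.where(r < 600, 0.3, np.where(r < 1200, 1.0, 0.0))
        vals = np.tile(sl[None, :, :], (8, 1, 1))
        return Volume(values=vals, voxel_size_um=voxel,
                      origin_um=(-half * voxel, -half * voxel, 0.0))

    def test_identical_sections_average_equals_single(self):
        vol = self._rim_core_volume()
        rep = whole_tumour_metrics(vol, thickness_um=200.0)  # 4-slice sections
        single = whole_tumour_metrics(vol, thickness_um=400.0)
        assert rep.regions["whole"]["mean"] == pytest.approx(
            single.regions["whole"]["mean"], rel=1e-9)

    def test_bright_rim_dark_core_ordering(self):
        rep = whole_tumour_metrics(self._rim_core_volume(), thickness_um=400.0)
        assert rep.regions["rim"]["mean"] > rep.regions["centre"]["mean"]
        assert 0.0 <= rep.relative_differences["mean"] <= 1.0

    def test_constant_masked_region(self):
        vals = np.zeros((4, 64, 64))
        vals[:, 16:48, 16:48] = 2.0
        vol = Volume(values=vals, voxel_size_um=50.0)
        rep = whole_tumour_metrics(vol, thickness_um=200.0)
        assert rep.regions["whole"]["variance"] == pytest.approx(0.0, abs=1e-12)
        assert rep.regions["whole"]["energy"] == pytest.approx(1.0, abs=1e-12)
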