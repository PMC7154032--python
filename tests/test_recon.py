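"""Backprojection reconstruction and image utilities."""

import numpy as np
import pytest

from msom.forward import FluenceModel, simulate_sinogram
from msom.phantom import Absorber, AbsorberScene, box_domain
from msom.recon import (
    ReconConfig,
    Volume,
    backproject,
    equalize_merge,
    estimate_sos,
    fluence_correct,
    measure_fwhm,
    mip,
)
from msom.scanner import ScanPlan

DOM = box_domain((8000.0,) * 3)
PLAN = ScanPlan(n_pulses=150)
CFG = ReconConfig(extent_um=(600.0, 600.0, 600.0), voxel_size_um=24.0,
                  use_derivative_term=True)


@pytest.fixture(scope="module")
def sphere_sinogram(request):
    scene = AbsorberScene([Absorber((0.0, 0.0, 0.0), 10.0, {"black": 1.0})], DOM)
    return simulate_sinogram(scene, plan=PLAN)


class TestBackproject:
    def test_peak_at_true_centre(self, sphere_sinogram):
        vol = backproject(sphere_sinogram, CFG)
        peak = np.unravel_index(np.argmax(vol.values), vol.shape)
        centre = tuple((s - 1) // 2 for s in vol.shape)
        assert all(abs(p - c) <= 1 for p, c in zip(peak, centre))

    def test_zero_sinogram_gives_zero_volume(self, sphere_sinogram):
        zero = sphere_sinogram.copy_with(np.zeros_like(sphere_sinogram.data))
        vol = backproject(zero, CFG)
        assert not np.any(vol.values)

    def test_linearity_in_the_sinogram(self, sphere_sinogram):
        doubled = sphere_sinogram.copy_with(2.0 * sphere_sinogram.data)
        v1 = backproject(sphere_sinogram, CFG)
        v2 = backproject(doubled, CFG)
        assert np.allclose(v2.values, 2.0 * v1.values, rtol=1e-5, atol=1e-12)

    def test_two_spheres_resolved_at_500um(self):
        scene = AbsorberScene([
            Absorber((-250.0, 0.0, 0.0), 10.0, {"black": 1.0}),
            Absorber((250.0, 0.0, 0.0), 10.0, {"black": 1.0}),
        ], DOM)
        sino = simulate_sinogram(scene, plan=PLAN)
        vol = backproject(sino, ReconConfig(extent_um=(960.0, 240.0, 240.0),
                                            voxel_size_um=24.0,
                                            use_derivative_term=True))
        iz, iy = (vol.shape[0] - 1) // 2, (vol.shape[1] - 1) // 2
        profile = vol.values[iz, iy, :]
        x = vol.axis_coords_um("x")
        left_peak = profile[x < 0].max()
        right_peak = profile[x > 0].max()
        x_l = x[x < 0][np.argmax(profile[x < 0])]
        x_r = x[x > 0][np.argmax(profile[x > 0])]
        assert abs(x_l + 250.0) <= 24.0 and abs(x_r - 250.0) <= 24.0
        trough = profile[(x > x_l) & (x < x_r)].min()
        assert trough < 0.5 * min(left_peak, right_peak)

    def test_rotational_consistency(self):
        # rotating the scene and the scan start angle together rotates the
        # reconstruction
        def recon_peak(offset_deg, pos):
            scene = AbsorberScene([Absorber(pos, 10.0, {"black": 1.0})], DOM)
            plan = ScanPlan(n_pulses=120, start_angle_deg=offset_deg)
            sino = simulate_sinogram(scene, plan=plan)
            cfg = ReconConfig(extent_um=(720.0, 720.0, 240.0), voxel_size_um=24.0,
                              use_derivative_term=True)
            vol = backproject(sino, cfg)
            iz, iy, ix = np.unravel_index(np.argmax(vol.values), vol.shape)
            return np.array([vol.axis_coords_um("x")[ix],
                             vol.axis_coords_um("y")[iy]])
        p0 = recon_peak(0.0, (200.0, 0.0, 0.0))
        p90 = recon_peak(90.0, (0.0, 200.0, 0.0))
        rotated = np.array([-p0[1], p0[0]])
        assert np.linalg.norm(p90 - rotated) <= 2 * 24.0


class TestEstimateSos:
    def test_recovers_true_speed(self, sphere_sinogram):
        cfg = ReconConfig(extent_um=(360.0, 360.0, 360.0), voxel_size_um=24.0)
        candidates = np.arange(1480.0, 1521.0, 4.0)
        best, crit = estimate_sos(sphere_sinogram, candidates, cfg)
        assert abs(best - 1500.0) <= 8.0  # within 0.5 % of the truth
        assert crit.shape == candidates.shape

    def test_search_excluding_truth_clamps_with_warning(self, sphere_sinogram):
        cfg = ReconConfig(extent_um=(360.0, 360.0, 360.0), voxel_size_um=24.0)
        with pytest.warns(UserWarning, match="boundary"):
            best, _ = estimate_sos(sphere_sinogram,
                                   np.arange(1540.0, 1581.0, 10.0), cfg)
        assert best == 1540.0

    def test_deterministic(self, sphere_sinogram):
        cfg = ReconConfig(extent_um=(360.0, 360.0, 360.0), voxel_size_um=24.0)
        cands = [1490.0, 1500.0, 1510.0]
        a, _ = estimate_sos(sphere_sinogram, cands, cfg)
        b, _ = estimate_sos(sphere_sinogram, cands, cfg)
        assert a == b

    def test_flat_criterion_raises(self, sphere_sinogram):
        zero = sphere_sinogram.copy_with(np.zeros_like(sphere_sinogram.data))
        cfg = ReconConfig(extent_um=(240.0, 240.0, 240.0), voxel_size_um=24.0)
        with pytest.raises(RuntimeError, match="flat criterion"):
            estimate_sos(zero, [1490.0, 1500.0, 1510.0], cfg)


class TestEqualizeMerge:
    def _vol(self, values):
        return Volume(values=values, voxel_size_um=24.0)

    def test_identical_inputs_identical_channels(self, rng):
        v = self._vol(rng.random((8, 8, 8)))
        low_n, high_n, comp = equalize_merge(v, self._vol(v.values.copy()))
        assert np.array_equal(low_n.values, high_n.values)
        assert comp.values.shape == (2, 8, 8, 8)

    def test_zero_high_band_leaves_low_channel(self, rng):
        low = self._vol(rng.random((6, 6, 6)))
        high = self._vol(np.zeros((6, 6, 6)))
        low_n, high_n, comp = equalize_merge(low, high)
        assert not np.any(comp.values[1])
        assert np.allclose(comp.values[0], low_n.values)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="grids"):
            equalize_merge(self._vol(rng.random((4, 4, 4))),
                           self._vol(rng.random((5, 5, 5))))


class TestFluenceCorrect:
    def test_zero_mu_is_identity(self, rng):
        v = Volume(values=rng.random((5, 5, 5)).astype(np.float32))
        out = fluence_correct(v, FluenceModel(mu_eff_per_mm=0.0))
        assert np.array_equal(out.values, v.values)

    def test_round_trip_with_forward_weighting(self):
        # a volume whose voxels carry the forward fluence decay is restored
        # to (near-)uniform intensity by the correction
        model = FluenceModel(mu_eff_per_mm=0.5, surface_radius_mm=3.0)
        base = Volume(values=np.ones((9, 9, 9), dtype=np.float32),
                      voxel_size_um=200.0, origin_um=(-800.0, -800.0, -800.0))
        weights = np.exp(-model.mu_eff_per_mm
                         * model.depths_mm(base.grid_positions_um()))
        forward = base.like((base.values * weights).astype(np.float32))
        corrected = fluence_correct(forward, model)
        spread = corrected.values.max() / corrected.values.min()
        assert spread <= 1.15

    def test_floor_bounds_amplification(self):
        model = FluenceModel(mu_eff_per_mm=10.0, surface_radius_mm=50.0)
        v = Volume(values=np.ones((3, 3, 3), dtype=np.float32),
                   voxel_size_um=24.0)
        out = fluence_correct(v, model, floor=1e-3)
        assert np.all(np.isfinite(out.values))
        assert out.values.max() <= 1.0 / 1e-3 + 1e-6


class TestMip:
    def test_single_voxel_slab_is_slice(self, rng):
        v = Volume(values=rng.random((6, 5, 4)), voxel_size_um=24.0)
        img = mip(v, axis="z", start_um=2 * 24.0, thickness_um=24.0)
        assert np.array_equal(img, v.values[2])

    def test_constant_volume(self):
        v = Volume(values=np.full((10, 10, 10), 3.0), voxel_size_um=24.0)
        assert np.all(mip(v, thickness_um=240.0) == 3.0)

    def test_hot_voxel_position(self):
        vals = np.zeros((10, 8, 8))
        vals[4, 5, 2] = 7.0
        v = Volume(values=vals, voxel_size_um=24.0)
        img = mip(v, axis="z", start_um=0.0, thickness_um=240.0)
        assert np.unravel_index(np.argmax(img), img.shape) == (5, 2)


class TestMeasureFwhm:
    @staticmethod
    def _gaussian_volume(sigma_um=30.0, voxel=6.0, n=61, offset=(0.0, 0.0, 0.0)):
        half = (n - 1) / 2.0
        coords = (np.arange(n) - half) * voxel
        zz, yy, xx = np.meshgrid(coords - offset[2], coords - offset[1],
                                 coords - offset[0], indexing="ij")
        vals = np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma_um**2))
        return Volume(values=vals, voxel_size_um=voxel,
                      origin_um=(-half * voxel,) * 3)

    def test_gaussian_blob_closed_form(self):
        vol = self._gaussian_volume()
        fw = measure_fwhm(vol, window_um=150.0)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 30.0  # 70.64 um
        for axis in ("x", "y", "z"):
            assert fw[axis] == pytest.approx(expected, abs=1.5)

    def test_sub_voxel_offset_robustness(self):
        a = measure_fwhm(self._gaussian_volume(), window_um=150.0)
        b = measure_fwhm(self._gaussian_volume(offset=(2.7, -1.9, 1.2)),
                         window_um=150.0)
        assert abs(a["x"] - b["x"]) / a["x"] <= 0.03
        assert abs(a["z"] - b["z"]) / a["z"] <= 0.03

    def test_peak_at_border_rejected(self):
        vals = np.zeros((21, 21, 21))
        vals[10, 10, 1] = 1.0
        vol = Volume(values=vals, voxel_size_um=6.0)
        with pytest.raises(ValueError, match="truncated"):
            measure_fwhm(vol, window_um=60.0)
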