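"""Analytic forward model and sinogram synthesis."""

import numpy as np
import pytest

from msom.forward import (
    FluenceModel,
    fluence_weight,
    impulse_response,
    simulate_sinogram,
    sphere_pressure,
)
from msom.phantom import Absorber, AbsorberScene, box_domain, load_spectra
from msom.scanner import ArraySpec, ScanPlan

DOM = box_domain((8000.0,) * 3)


class TestSpherePressure:
    def test_bipolar_n_shape_and_duration(self):
        t = np.linspace(0.9, 1.1, 20001)
        p = sphere_pressure(10.0, 1500.0, 1.0, 1500.0, t)
        nz = np.nonzero(p)[0]
        duration_ns = (t[nz[-1]] - t[nz[0]]) * 1e3
        assert duration_ns == pytest.approx(2 * 10.0 / 1500.0 * 1e3, rel=0.01)
        assert p[nz[0]] > 0 and p[nz[-1]] < 0  # positive then negative

    def test_zero_amplitude_gives_zero_trace(self):
        t = np.linspace(0.0, 2.0, 1000)
        assert not np.any(sphere_pressure(10.0, 1500.0, 0.0, 1500.0, t))

    def test_trace_integrates_to_zero(self):
        # time axis symmetric about the arrival time, so the quadrature of
        # the odd analytic form is exact up to rounding
        tau = 1200.0 / 1480.0
        t = tau + np.linspace(-0.5, 0.5, 200001)
        p = sphere_pressure(25.0, 1200.0, 3.0, 1480.0, t)
        scale = np.abs(p).max() * (2 * 25.0 / 1480.0)
        assert abs(np.trapezoid(p, t)) < 1e-10 * scale

    def test_detector_inside_sphere_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            sphere_pressure(100.0, 50.0, 1.0, 1500.0, np.linspace(0, 1, 10))


class TestImpulseResponse:
    def test_spectrum_peaks_at_centre_frequency(self):
        k = impulse_response(ArraySpec(), 2048, 0.008)
        H = np.abs(np.fft.rfft(np.fft.ifftshift(k)))
        f = np.fft.rfftfreq(2048, 0.008)
        assert abs(f[np.argmax(H)] - 15.0) < 0.1

    def test_minus_6dB_width_is_45_percent(self):
        # -6 dB (half amplitude) at fc +- 0.45 * fc / 2, verified by FFT
        k = impulse_response(ArraySpec(), 4096, 0.008)
        H = np.abs(np.fft.rfft(np.fft.ifftshift(k)))
        f = np.fft.rfftfreq(4096, 0.008)
        lo, hi = np.interp([15.0 - 3.375, 15.0 + 3.375], f, H)
        assert lo == pytest.approx(0.5 * H.max(), rel=0.02)
        assert hi == pytest.approx(0.5 * H.max(), rel=0.02)

    def test_convolution_with_delta_is_identity(self):
        k = impulse_response(ArraySpec(), 512, 0.008)
        delta = np.zeros(512)
        delta[256] = 1.0
        out = np.convolve(delta, k)[256:256 + 512]
        assert np.allclose(out, k, atol=1e-15)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            impulse_response(ArraySpec(), 512, 0.05)  # 20 MS/s


class TestFluence:
    def test_surface_weight_is_one(self):
        m = FluenceModel(mu_eff_per_mm=0.7, surface_radius_mm=6.0)
        assert fluence_weight((6000.0, 0.0, 0.0), m) == 1.0

    def test_zero_mu_eff(self):
        m = FluenceModel(mu_eff_per_mm=0.0)
        assert fluence_weight((0.0, 0.0, 0.0), m) == 1.0

    def test_closed_form_decay(self):
        # depth 2 mm at mu_eff = 0.5 /mm -> e^-1
        m = FluenceModel(mu_eff_per_mm=0.5, surface_radius_mm=6.0)
        w = fluence_weight((4000.0, 0.0, 0.0), m)
        assert w == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            FluenceModel(mu_eff_per_mm=-0.1)


class TestSimulateSinogram:
    plan = ScanPlan(n_pulses=4, n_samples=1024, t_start_us=1.0)

    def test_empty_scene_noiseless_is_zero(self):
        scene = AbsorberScene([], DOM)
        with pytest.warns(UserWarning, match="empty scene"):
            s = simulate_sinogram(scene, plan=ScanPlan(n_pulses=2, n_samples=256))
        assert not np.any(s.data)

    def test_first_arrival_matches_time_of_flight(self):
        scene = AbsorberScene([Absorber((0.0, 0.0, 0.0), 200.0, {"black": 1.0})],
                              DOM)
        s = simulate_sinogram(scene, plan=ScanPlan(n_pulses=5), apply_ir=False,
                              elevation_weighting=False)
        c, dt, t0 = 1500.0, s.dt_us, s.plan.t_start_us
        for p in range(5):
            for e in range(0, 96, 13):
                d = np.linalg.norm(s.poses.positions[p, e])
                expected = int(np.ceil((d / c - 200.0 / c - t0) / dt))
                first = np.nonzero(np.abs(s.data[p, e]) > 0)[0][0]
                assert abs(int(first) - expected) <= 1

    def test_determinism_under_fixed_seed(self, single_sphere_scene):
        kw = dict(plan=self.plan, noise_sd=0.05, seed=42)
        a = simulate_sinogram(single_sphere_scene, **kw)
        b = simulate_sinogram(single_sphere_scene, **kw)
        assert np.array_equal(a.data, b.data)

    def test_linearity_of_disjoint_scenes(self):
        a1 = AbsorberScene([Absorber((300.0, 0.0, 0.0), 50.0, {"black": 1.0})], DOM)
        a2 = AbsorberScene([Absorber((-300.0, 0.0, -200.0), 50.0, {"black": 2.0})],
                           DOM)
        both = AbsorberScene(a1.absorbers + a2.absorbers, DOM)
        kw = dict(plan=self.plan)
        sA = simulate_sinogram(a1, **kw)
        sB = simulate_sinogram(a2, **kw)
        sAB = simulate_sinogram(both, **kw)
        err = np.abs(sAB.data - (sA.data + sB.data)).max()
        assert err <= 1e-6 * np.abs(sAB.data).max()

    def test_wavelength_consistency_pure_hbo2(self):
        spectra = load_spectra()
        scene = AbsorberScene([Absorber((0.0, 0.0, 0.0), 50.0, {"HbO2": 1.0})],
                              DOM)
        s710 = simulate_sinogram(scene, spectra, 710.0, plan=self.plan)
        s850 = simulate_sinogram(scene, spectra, 850.0, plan=self.plan)
        ratio = (np.linalg.norm(s710.data.astype(np.float64))
                 / np.linalg.norm(s850.data.astype(np.float64)))
        expected = spectra.value("HbO2", 710.0) / spectra.value("HbO2", 850.0)
        assert ratio == pytest.approx(expected, rel=1e-6)

    def test_fluence_scales_amplitude(self):
        scene = AbsorberScene([Absorber((0.0, 0.0, 0.0), 50.0, {"black": 1.0})],
                              DOM)
        ref = simulate_sinogram(scene, plan=self.plan)
        model = FluenceModel(mu_eff_per_mm=0.5, surface_radius_mm=6.0)
        att = simulate_sinogram(scene, plan=self.plan, fluence=model)
        # absorber on the axis: depth 6 mm -> weight e^-3
        ratio = np.abs(att.data).max() / np.abs(ref.data).max()
        assert ratio == pytest.approx(np.exp(-3.0), rel=1e-5)
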