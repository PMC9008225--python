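import numpy as np
import pytest

from holomea.holography import (
    SLMSpec,
    calibrate_mapping,
    fit_focus,
    focus_position_um,
    fresnel_zone_plate,
    min_focus_distance,
    propagate,
    register_electrode_grids,
    synthesize_hologram,
    working_distance,
)

# Reduced-resolution modulator for propagation tests: same pixel pitch and
# wavelength as the full device, fewer pixels.
SMALL = SLMSpec(n_rows=256, n_cols=256)
F_TEST = 0.100  # m, comfortably above the small grid's aliasing bound


class TestFresnelZonePlate:
    def test_phase_zero_at_center_pixel(self):
        field = fresnel_zone_plate(F_TEST, SMALL)
        assert np.isclose(np.angle(field[128, 128]), 0.0)

    def test_radial_symmetry(self):
        field = fresnel_zone_plate(F_TEST, SMALL)
        p = np.angle(field)
        assert np.allclose(p[128, 128 + 40], p[128, 128 - 40])
        assert np.allclose(p[128 + 40, 128], p[128 - 40, 128])
        assert np.allclose(p[128 + 40, 128], p[128, 128 + 40])

    def test_aliasing_guard(self):
        with pytest.raises(ValueError, match="alias"):
            fresnel_zone_plate(0.005, SMALL)

    def test_binarized_fzp_focuses_on_axis(self):
        holo = synthesize_hologram([(0.0, 0.0)], F_TEST, SMALL)
        intensity = propagate(holo, F_TEST, SMALL)
        r, c = np.unravel_index(np.argmax(intensity), intensity.shape)
        assert abs(r - 128) <= 1 and abs(c - 128) <= 1
        assert intensity.max() / intensity.mean() > 100


class TestSynthesizeHologram:
    def test_single_on_axis_target_reduces_to_binary_fzp(self):
        holo = synthesize_hologram([(0.0, 0.0)], F_TEST, SMALL)
        fzp = fresnel_zone_plate(F_TEST, SMALL)
        expected = np.where(fzp.real >= 0, 0.0, np.pi)
        assert np.array_equal(holo.phase, expected)

    def test_off_axis_focus_lands_on_target(self):
        target = (60.0, -45.0)  # sample-plane um
        holo = synthesize_hologram([target], F_TEST, SMALL)
        intensity = propagate(holo, F_TEST, SMALL)
        fx, fy = focus_position_um(intensity, SMALL)
        demag_px = SMALL.pixel_pitch_um * SMALL.beta
        assert abs(fx - target[0]) <= demag_px
        assert abs(fy - target[1]) <= demag_px

    def test_two_targets_two_foci(self):
        t1, t2 = (80.0, 0.0), (-80.0, 40.0)
        holo = synthesize_hologram([t1, t2], F_TEST, SMALL)
        intensity = propagate(holo, F_TEST, SMALL)
        demag_px = SMALL.pixel_pitch_um * SMALL.beta
        for tx, ty in (t1, t2):
            c = int(round(tx / demag_px)) + 128
            r = int(round(ty / demag_px)) + 128
            patch = intensity[r - 2 : r + 3, c - 2 : c + 3]
            assert patch.max() > 20 * intensity.mean()

    def test_error_diffusion_at_least_matches_threshold_contrast(self):
        targets = [(80.0, 0.0), (-80.0, 40.0)]
        ratios = {}
        for method in ("threshold", "error_diffusion"):
            holo = synthesize_hologram(targets, F_TEST, SMALL, method=method)
            intensity = propagate(holo, F_TEST, SMALL)
            ratios[method] = intensity.max() / intensity.mean()
        assert ratios["error_diffusion"] >= ratios["threshold"] * 0.9

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synthesize_hologram([], F_TEST, SMALL)

    def test_out_of_field_target_rejected(self):
        with pytest.raises(ValueError, match="addressable"):
            synthesize_hologram([(10_000.0, 0.0)], F_TEST, SMALL)

    def test_phase_values_are_binary(self):
        holo = synthesize_hologram([(40.0, 20.0)], F_TEST, SMALL,
                                   method="error_diffusion")
        assert set(np.unique(holo.phase)) <= {0.0, np.pi}


class TestOpticsArithmetic:
    def test_min_focus_distance_formula(self):
        # beta=1, N=2, pitch=1 um, lambda=0.5 um -> 2 um
        spec = SLMSpec(n_rows=2, n_cols=4, pixel_pitch_um=1.0,
                       wavelength_nm=500.0, beta=1.0)
        assert np.isclose(min_focus_distance(spec), 2e-6)

    def test_doubling_wavelength_halves_f_min(self):
        a = SLMSpec(wavelength_nm=450.0)
        b = SLMSpec(wavelength_nm=900.0)
        assert np.isclose(min_focus_distance(a), 2 * min_focus_distance(b))

    def test_f_min_of_production_modulator(self):
        # beta N pitch^2 / (2 lambda) with the QXGA-class constants
        spec = SLMSpec()
        expected = (1 / 7.2) * 1536 * (8.2e-6) ** 2 / (2 * 450e-9)
        assert np.isclose(min_focus_distance(spec), expected)
        assert np.isclose(min_focus_distance(spec), 15.94e-3, rtol=1e-3)

    def test_working_distance_is_the_sum(self):
        assert np.isclose(working_distance(6.4e-3, 25e-3), 31.4e-3)
        assert working_distance(0.0, 0.025) == 0.025
        assert working_distance(0.01, 0.02) == working_distance(0.02, 0.01)


class TestPropagate:
    def test_uniform_phase_stays_unfocused(self):
        # a flat phase is a plane wave: propagation produces no focus, so
        # the peak-to-mean contrast stays tiny compared with a zone plate
        flat = propagate(np.zeros((256, 256)), F_TEST, SMALL)
        holo = synthesize_hologram([(0.0, 0.0)], F_TEST, SMALL)
        focused = propagate(holo, F_TEST, SMALL)
        flat_ratio = flat.max() / flat.mean()
        focus_ratio = focused.max() / focused.mean()
        assert focus_ratio > 20 * flat_ratio

    def test_energy_conservation_parseval(self):
        spec = SLMSpec(128, 128)
        phase = np.where(np.random.default_rng(0).random((128, 128)) > 0.5,
                         np.pi, 0.0)
        # compare energy on the padded grid before and after the transfer step
        pad = 2
        u = np.zeros((128 * pad, 128 * pad), complex)
        u[64:192, 64:192] = np.exp(1j * phase)
        e_in = (np.abs(u) ** 2).sum()
        # the cropped intensity returned by propagate() is not
        # energy-complete; check the unitary transfer step directly
        lam = spec.wavelength_m
        fy = np.fft.fftfreq(128 * pad, spec.pitch_m)[:, None]
        fx = np.fft.fftfreq(128 * pad, spec.pitch_m)[None, :]
        arg = 1 / lam**2 - fx**2 - fy**2
        h = np.where(arg > 0, np.exp(1j * 2 * np.pi * np.sqrt(np.maximum(arg, 0)) * 0.05), 0)
        uz = np.fft.ifft2(np.fft.fft2(u) * h)
        e_out = (np.abs(uz) ** 2).sum()
        assert abs(e_out - e_in) / e_in < 1e-6

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            propagate(np.zeros((64, 64)), -1.0, SLMSpec(64, 64))


class TestFitFocus:
    def test_recovers_center_of_noiseless_gaussian(self):
        y, x = np.mgrid[0:96, 0:96]
        img = 5.0 * np.exp(-(((x - 12.3) ** 2) + (y - 45.6) ** 2) / (2 * 2.0**2))
        fit = fit_focus(img)
        assert abs(fit.center_xy[0] - 12.3) < 0.05
        assert abs(fit.center_xy[1] - 45.6) < 0.05
        assert abs(fit.sigma_xy[0] - 2.0) < 0.05

    def test_width_ratio_is_gaussian_identity(self):
        y, x = np.mgrid[0:64, 0:64]
        img = np.exp(-(((x - 30) ** 2) + (y - 33) ** 2) / (2 * 3.0**2))
        fit = fit_focus(img)
        ratio = fit.one_over_e2_width_xy[0] / fit.fwhm_xy[0]
        assert np.isclose(ratio, 4.0 / (2 * np.sqrt(2 * np.log(2))), rtol=1e-6)

    def test_isotropic_input_isotropic_widths(self):
        y, x = np.mgrid[0:64, 0:64]
        img = np.exp(-(((x - 30) ** 2) + (y - 30) ** 2) / (2 * 4.0**2))
        fit = fit_focus(img)
        assert np.isclose(fit.sigma_xy[0], fit.sigma_xy[1], rtol=1e-6)


class TestCalibration:
    def test_identity_mapping_recovered_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-100, 100, (10, 2))
        fit = calibrate_mapping(pts, pts)
        assert fit.residual_rms < 1e-9
        assert np.allclose(fit.predict(pts), pts, atol=1e-9)

    def test_known_quadratic_warp_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1, 1, (20, 2))
        x, y = pts[:, 0], pts[:, 1]
        warped = np.column_stack([
            1.0 + 2.0 * x - 0.3 * y + 0.1 * x**2 + 0.05 * x * y - 0.2 * y**2,
            -0.5 + 0.1 * x + 1.8 * y - 0.07 * x**2 + 0.02 * x * y + 0.3 * y**2,
        ])
        fit = calibrate_mapping(pts, warped)
        assert fit.residual_rms < 1e-9
        probe = rng.uniform(-1, 1, (5, 2))
        px, py = probe[:, 0], probe[:, 1]
        expected = np.column_stack([
            1.0 + 2.0 * px - 0.3 * py + 0.1 * px**2 + 0.05 * px * py - 0.2 * py**2,
            -0.5 + 0.1 * px + 1.8 * py - 0.07 * px**2 + 0.02 * px * py + 0.3 * py**2,
        ])
        assert np.allclose(fit.predict(probe), expected, atol=1e-9)

    def test_five_pairs_underdetermined(self):
        pts = np.random.default_rng(3).uniform(0, 1, (5, 2))
        with pytest.raises(ValueError, match="6 point"):
            calibrate_mapping(pts, pts)

    def test_collinear_points_rejected(self):
        x = np.linspace(0, 1, 8)
        pts = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_mapping(pts, pts)


class TestRegistration:
    @staticmethod
    def grid_centroids():
        g = np.mgrid[0:8, 0:8].reshape(2, -1).T.astype(float) * 50.0
        return g

    def test_identity(self):
        g = self.grid_centroids()
        t = register_electrode_grids(g, g)
        assert np.allclose(t.matrix, np.eye(2), atol=1e-12)
        assert np.allclose(t.offset, 0, atol=1e-9)

    def test_rotation_and_scale_recovered(self):
        g = self.grid_centroids()
        theta = np.deg2rad(10.0)
        rot = 1.2 * np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
        moved = g @ rot.T + np.array([5.0, -3.0])
        t = register_electrode_grids(g, moved)
        assert np.allclose(t.matrix, rot, atol=1e-6)
        assert np.allclose(t.offset, [5.0, -3.0], atol=1e-6)
        assert np.allclose(t.inverse().apply(moved), g, atol=1e-6)

    def test_noise_floor_residual(self):
        rng = np.random.default_rng(4)
        g = self.grid_centroids()
        noise = rng.normal(0, 0.5, g.shape)
        t = register_electrode_grids(g, g + noise)
        # LS residual RMS ~ noise SD (within a factor reflecting dof)
        assert 0.2 < t.residual_rms < 0.8

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 matched"):
            register_electrode_grids(np.zeros((2, 2)), np.zeros((2, 2)))


def test_calibration_round_trip_through_the_optical_chain():
    """sample -> SLM -> hologram -> propagation -> focus fit -> sample
    returns the starting point within the fit tolerance."""
    spec = SMALL
    rng = np.random.default_rng(9)
    # calibration pairs from the physical model: SLM centre = sample / beta
    sample_pts = rng.uniform(-100, 100, (12, 2))
    slm_pts = sample_pts / spec.beta
    fit = calibrate_mapping(sample_pts, slm_pts)

    start = np.array([55.0, -70.0])
    slm_xy = fit.predict(start)[0]  # um in the SLM plane
    target_sample = (slm_xy[0] * spec.beta, slm_xy[1] * spec.beta)
    holo = synthesize_hologram([target_sample], F_TEST, spec)
    intensity = propagate(holo, F_TEST, spec)

    r, c = np.unravel_index(np.argmax(intensity), intensity.shape)
    patch = intensity[r - 6 : r + 7, c - 6 : c + 7]
    gfit = fit_focus(patch)
    col = c - 6 + gfit.center_xy[0]
    row = r - 6 + gfit.center_xy[1]
    x_um = (col - spec.n_cols // 2) * spec.pixel_pitch_um * spec.beta
    y_um = (row - spec.n_rows // 2) * spec.pixel_pitch_um * spec.beta
    demag_px = spec.pixel_pitch_um * spec.beta
    assert abs(x_um - start[0]) <= demag_px
    assert abs(y_um - start[1]) <= demag_px
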