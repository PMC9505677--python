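"""Forward instrument model: passbands, endmembers, scenes, exposures,
raw-cube synthesis and its radiometric invariants."""

import numpy as np
import pytest

from foulscan import simulate as sim
from foulscan.hsio import build_wavelength_grid


def measure_fwhm(curve, grid):
    """Numeric full width at half maximum by linear interpolation."""
    half = curve.max() / 2.0
    above = np.where(curve >= half)[0]
    lo, hi = above[0], above[-1]

    def cross(below, above):
        return np.interp(half, [curve[below], curve[above]], [grid[below], grid[above]])

    left = cross(lo - 1, lo) if lo > 0 else grid[lo]
    right = cross(hi + 1, hi) if hi < len(grid) - 1 else grid[hi]
    return right - left


class TestPassband:
    @pytest.mark.parametrize("cwl,peak,fwhm", [(420.0, 0.0072, 6.8), (730.0, 0.236, 14.4)])
    def test_endpoint_peak_and_width(self, cwl, peak, fwhm):
        band = sim.lctf_passband(sim.LCTFModel(), cwl)
        assert band.max() == pytest.approx(peak, rel=1e-9)
        assert measure_fwhm(band, sim.FINE_GRID_NM) == pytest.approx(fwhm, abs=1.0)

    def test_interpolated_width_at_575(self):
        band = sim.lctf_passband(sim.LCTFModel(), 575.0)
        expected = sim.LCTFModel().fwhm(575.0)
        assert measure_fwhm(band, sim.FINE_GRID_NM) == pytest.approx(expected, abs=1.0)

    def test_width_and_peak_increase_with_cwl(self):
        lctf = sim.LCTFModel()
        fw = [lctf.fwhm(c) for c in (450, 550, 650)]
        pk = [lctf.peak_transmission(c) for c in (450, 550, 650)]
        assert fw == sorted(fw) and pk == sorted(pk)

    def test_out_of_range_cwl_rejected(self):
        with pytest.raises(ValueError):
            sim.lctf_passband(sim.LCTFModel(), 410.0)


def local_min_in_window(curve, center, half_width):
    """True if the curve has an interior local minimum within the window."""
    sel = (sim.FINE_GRID_NM >= center - half_width) & (sim.FINE_GRID_NM <= center + half_width)
    idx = np.where(sel)[0]
    inner = curve[idx[0] - 5 : idx[-1] + 6]
    k = int(np.argmin(inner))
    return 0 < k < len(inner) - 1


class TestEndmembers:
    def test_white_panel_is_flat_near_045(self):
        em = sim.generate_endmember("panel_white", seed=0, dip_depth_jitter=0)
        assert em.reflectance.mean() == pytest.approx(0.45, abs=0.02)
        assert em.reflectance.std() < 0.01

    def test_mussel_is_dark(self):
        em = sim.generate_endmember("mussel", seed=0, dip_depth_jitter=0)
        assert em.reflectance.mean() == pytest.approx(0.04, abs=0.02)

    @pytest.mark.parametrize("cls", ["green_algae", "red_algae", "brown_algae"])
    def test_algae_have_chlorophyll_dips(self, cls):
        em = sim.generate_endmember(cls, seed=3)
        assert local_min_in_window(em.reflectance, 450, 10)
        assert local_min_in_window(em.reflectance, 665, 15)

    def test_red_algae_satellite_dip_at_615(self):
        em = sim.generate_endmember("red_algae", seed=3)
        assert local_min_in_window(em.reflectance, 615, 15)

    @pytest.mark.parametrize("cls", ["green_algae", "red_algae", "brown_algae"])
    def test_algae_dark_outside_fluorescence_peak(self, cls):
        em = sim.generate_endmember(cls, seed=0, dip_depth_jitter=0)
        band = (sim.FINE_GRID_NM >= 420) & (sim.FINE_GRID_NM <= 700)
        assert em.reflectance[band].max() < 0.16

    def test_same_seed_gives_identical_curves(self):
        a = sim.generate_endmember("green_algae", seed=7)
        b = sim.generate_endmember("green_algae", seed=7)
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_species_share_group_features(self):
        ulva = sim.generate_endmember("Ulva", seed=1)
        assert local_min_in_window(ulva.reflectance, 450, 10)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_endmember("kelp_forest", seed=0)


class TestScene:
    def _ems(self):
        return {
            "panel_white": sim.generate_endmember("panel_white", seed=0),
            "green_algae": sim.generate_endmember("green_algae", seed=1),
        }

    def test_coverage_counts_come_from_raster(self):
        ems = self._ems()
        layout = [sim.ShapeSpec("rectangle", "green_algae", (50, 50), (50, 50))]
        scene = sim.generate_scene(layout, ems, (100, 100), "panel_white", seed=0)
        cov = scene.true_coverage()
        assert cov["green_algae"] == pytest.approx(25.0)
        assert cov["panel_white"] == pytest.approx(75.0)

    def test_empty_layout_is_all_panel(self):
        scene = sim.generate_scene([], self._ems(), (20, 20), "panel_white", seed=0)
        assert scene.true_coverage()["panel_white"] == 100.0

    def test_fixed_seed_reproduces_scene(self):
        ems = self._ems()
        layout = [sim.ShapeSpec("blob", "green_algae", (10, 10), (5, 6))]
        a = sim.generate_scene(layout, ems, (20, 20), "panel_white", seed=5)
        b = sim.generate_scene(layout, ems, (20, 20), "panel_white", seed=5)
        assert np.array_equal(a.label_map.labels, b.label_map.labels)
        assert np.array_equal(a.brightness, b.brightness)

    def test_later_shape_wins_overlap(self):
        ems = dict(self._ems(), red_algae=sim.generate_endmember("red_algae", seed=2))
        layout = [
            sim.ShapeSpec("rectangle", "green_algae", (10, 10), (20, 20)),
            sim.ShapeSpec("rectangle", "red_algae", (10, 10), (20, 20)),
        ]
        scene = sim.generate_scene(layout, ems, (20, 20), "panel_white", seed=0)
        assert scene.true_coverage()["red_algae"] == 100.0
        assert scene.true_coverage()["green_algae"] == 0.0

    def test_realized_reflectance_is_nonnegative(self):
        scene = sim.generate_scene(
            [sim.ShapeSpec("ellipse", "green_algae", (10, 10), (6, 8))],
            self._ems(), (20, 20), "panel_white", seed=2,
        )
        assert np.all(scene.realized_reflectance() >= 0)


class TestExposurePlanning:
    def test_doubling_radiance_halves_every_exposure(self, instrument, grid63):
        base = sim.plan_exposures(instrument, grid63, 0.45, 0.5)
        brighter = sim.plan_exposures(
            sim.default_instrument(led_radiance_scale=2 * instrument.led_radiance_scale),
            grid63, 0.45, 0.5,
        )
        np.testing.assert_allclose(base.t_exp_s, 2 * brighter.t_exp_s)

    def test_target_fill_scales_linearly(self, instrument, grid63):
        half = sim.plan_exposures(instrument, grid63, 0.45, 0.5)
        quarter = sim.plan_exposures(instrument, grid63, 0.45, 0.25)
        np.testing.assert_allclose(half.t_exp_s, 2 * quarter.t_exp_s)

    def test_extreme_channels_need_longer_exposures(self, plan, grid63):
        t = dict(zip(grid63.centers, plan.t_exp_s))
        assert t[430.0] > t[550.0]
        assert t[730.0] > t[600.0]

    def test_invalid_fill_rejected(self, instrument, grid63):
        with pytest.raises(ValueError):
            sim.plan_exposures(instrument, grid63, 0.45, 1.5)


class TestRawCube:
    def test_dark_mode_is_exact_dark_counts(self, flat_scene, instrument, plan):
        cube = sim.simulate_raw_cube(flat_scene, instrument, plan, "dark", noise=False)
        expected = plan.t_exp_s[None, None, :] * instrument.dark_current_rate
        assert np.array_equal(cube.data, np.broadcast_to(expected, cube.shape))

    def test_zero_reflectance_scene_equals_dark(self, instrument, plan):
        ems = {"void": sim.EndmemberSpectrum("void", np.zeros(sim.FINE_GRID_NM.shape))}
        scene = sim.generate_scene([], ems, (8, 8), "void", seed=0, brightness_jitter=0.0)
        dark = sim.simulate_raw_cube(scene, instrument, plan, "dark", noise=False)
        black = sim.simulate_raw_cube(scene, instrument, plan, "scene", noise=False)
        np.testing.assert_array_equal(black.data, dark.data)

    def test_uniform_scene_at_rref_equals_reference(self, instrument, plan):
        ems = {"std": sim.EndmemberSpectrum("std", np.full(sim.FINE_GRID_NM.shape, 0.10))}
        scene = sim.generate_scene([], ems, (8, 8), "std", seed=0, brightness_jitter=0.0)
        as_scene = sim.simulate_raw_cube(scene, instrument, plan, "scene", noise=False)
        as_ref = sim.simulate_raw_cube(
            scene, instrument, plan, "reference", ref_reflectance=0.10, noise=False
        )
        np.testing.assert_allclose(as_scene.data, as_ref.data, rtol=1e-12)

    def test_counts_linear_in_exposure_gain_and_reflectance(self, flat_scene, instrument, grid63):
        plan = sim.plan_exposures(instrument, grid63, 0.45, 0.3)  # headroom for 2x gain
        dark = plan.t_exp_s[None, None, :] * instrument.dark_current_rate
        base = sim.simulate_raw_cube(flat_scene, instrument, plan, "scene", noise=False)
        sig = base.data - dark
        plan2 = sim.ExposurePlan(plan.grid, 0.5 * plan.t_exp_s)
        half_t = sim.simulate_raw_cube(flat_scene, instrument, plan2, "scene", noise=False)
        np.testing.assert_allclose(half_t.data - 0.5 * dark, 0.5 * sig, rtol=1e-9)
        inst2 = sim.default_instrument(em_gain=2 * instrument.em_gain)
        double_g = sim.simulate_raw_cube(flat_scene, inst2, plan, "scene", noise=False)
        np.testing.assert_allclose(double_g.data - dark, 2 * sig, rtol=1e-9)

    def test_counts_never_exceed_adc_ceiling(self, flat_scene, instrument, grid63):
        plan = sim.plan_exposures(instrument, grid63, 0.05, 0.9)  # gross overexposure
        cube = sim.simulate_raw_cube(flat_scene, instrument, plan, "scene", noise=True, seed=0)
        assert cube.data.max() <= 2**14 - 1
        assert cube.data.min() >= 0

    def test_noise_off_is_deterministic(self, flat_scene, instrument, plan):
        a = sim.simulate_raw_cube(flat_scene, instrument, plan, "scene", noise=False)
        b = sim.simulate_raw_cube(flat_scene, instrument, plan, "scene", noise=False)
        assert np.array_equal(a.data, b.data)

    def test_snr_scales_with_sqrt_exposure(self, instrument, grid63):
        """Quadrupling one channel's exposure doubles the per-pixel SNR."""
        ems = {"std": sim.EndmemberSpectrum("std", np.full(sim.FINE_GRID_NM.shape, 0.10))}
        scene = sim.generate_scene([], ems, (110, 110), "std", seed=0, brightness_jitter=0.0)
        plan1 = sim.plan_exposures(instrument, grid63, 0.45, 0.2)
        t4 = plan1.t_exp_s.copy()
        ch = grid63.index_of(550.0)
        t4[ch] *= 4
        plan4 = sim.ExposurePlan(grid63, t4)

        def snr(plan, seed):
            noisy = sim.simulate_raw_cube(scene, instrument, plan, "scene", noise=True, seed=seed)
            clean = sim.simulate_raw_cube(scene, instrument, plan, "scene", noise=False)
            resid = (noisy.data - clean.data)[:, :, ch]
            return clean.data[:, :, ch].mean() / resid.std()

        ratio = snr(plan4, 11) / snr(plan1, 12)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_negative_exposure_rejected(self, grid63):
        with pytest.raises(ValueError):
            sim.ExposurePlan(grid63, -np.ones(63))
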