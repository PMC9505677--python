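"""Two-point reflectance transform, validity masking and SG smoothing."""

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from foulscan import calibrate as cal
from foulscan import simulate as sim
from foulscan.hsio import Hypercube, build_wavelength_grid
from conftest import acquire_triple


def small_calset(scene, bright, dark, grid, r_ref=0.10):
    mk = lambda a: Hypercube(np.asarray(a, dtype=float), grid, "raw_counts")
    return cal.CalibrationSet(mk(scene), mk(bright), mk(dark), r_ref)


class TestReflectanceTransform:
    def test_scene_equal_to_bright_recovers_rref(self):
        grid = build_wavelength_grid(500, 520, 5)
        counts = np.full((4, 4, 5), 1000.0)
        refl = cal.reflectance_transform(small_calset(counts, counts, np.zeros_like(counts), grid))
        assert refl.valid.all()
        np.testing.assert_allclose(refl.data, 0.10)

    def test_scene_equal_to_dark_recovers_zero(self):
        grid = build_wavelength_grid(500, 520, 5)
        dark = np.full((4, 4, 5), 50.0)
        bright = np.full((4, 4, 5), 2000.0)
        refl = cal.reflectance_transform(small_calset(dark, bright, dark, grid))
        assert refl.valid.all()
        np.testing.assert_array_equal(refl.data, 0.0)

    def test_flat_patch_recovered_exactly(self, flat_scene, flat_reflectance):
        """Noise-free forward-model round trip: flat spectra are
        passband-exact under the two-point transform."""
        labels = flat_scene.label_map
        m30 = labels.labels == labels.code_of("flat30")
        assert np.abs(flat_reflectance.data[m30] - 0.30).max() < 1e-9
        m08 = labels.labels == labels.code_of("flat08")
        assert np.abs(flat_reflectance.data[m08] - 0.08).max() < 1e-9

    def test_dead_bright_entry_is_isolated(self):
        grid = build_wavelength_grid(500, 520, 5)
        bright = np.full((4, 4, 5), 2000.0)
        bright[1, 2, 3] = 0.0  # bright == dark there
        refl = cal.reflectance_transform(small_calset(np.full((4, 4, 5), 800.0), bright, np.zeros((4, 4, 5)), grid))
        assert not refl.valid[1, 2, 3]
        expected = np.ones((4, 4, 5), dtype=bool)
        expected[1, 2, 3] = False
        assert np.array_equal(refl.valid, expected)

    def test_negative_numerator_clipped_and_flagged(self):
        grid = build_wavelength_grid(500, 520, 5)
        scene = np.full((2, 2, 5), 40.0)
        scene[0, 0, 0] = 10.0  # below dark level
        refl = cal.reflectance_transform(
            small_calset(scene, np.full((2, 2, 5), 2000.0), np.full((2, 2, 5), 20.0), grid)
        )
        assert refl.data[0, 0, 0] == 0.0
        assert refl.clipped[0, 0, 0]
        assert refl.clipped.sum() == 1

    def test_dimension_mismatch_rejected(self, grid63):
        a = Hypercube(np.zeros((4, 4, 63)), grid63)
        b = Hypercube(np.zeros((5, 4, 63)), grid63)
        with pytest.raises(ValueError):
            cal.CalibrationSet(a, b, a)

    def test_rref_out_of_range_rejected(self, grid63):
        a = Hypercube(np.zeros((2, 2, 63)), grid63)
        with pytest.raises(ValueError):
            cal.CalibrationSet(a, a, a, r_ref=1.5)

    def test_matches_scalar_loop_oracle_bitwise(self):
        """Entry-by-entry scalar recomputation agrees with the vectorized
        transform bit-for-bit on a small cube."""
        grid = build_wavelength_grid(500, 520, 5)
        rng = np.random.default_rng(42)
        scene = rng.uniform(0, 3000, (8, 8, 5))
        bright = rng.uniform(0, 3000, (8, 8, 5))
        dark = rng.uniform(0, 60, (8, 8, 5))
        refl = cal.reflectance_transform(small_calset(scene, bright, dark, grid))
        for r in range(8):
            for c in range(8):
                for ch in range(5):
                    denom = bright[r, c, ch] - dark[r, c, ch]
                    if denom <= cal.DEFAULT_DENOM_GUARD:
                        assert not refl.valid[r, c, ch]
                        continue
                    numer = max(scene[r, c, ch] - dark[r, c, ch], 0.0)
                    assert refl.data[r, c, ch] == 0.10 * numer / denom

    def test_flat_field_invariance(self, flat_scene, instrument, plan, flat_reflectance):
        """Any positive spatial illumination field cancels pixel-wise."""

        class Shaded(sim.InstrumentModel):
            def illumination_profile(self, rows, cols):
                base = super().illumination_profile(rows, cols)
                return base * (0.5 + 0.5 * np.linspace(0.0, 1.0, cols)[None, :])

        refl2 = cal.reflectance_transform(acquire_triple(flat_scene, Shaded(), plan))
        assert refl2.valid.all()
        assert np.abs(refl2.data - flat_reflectance.data).max() < 1e-12

    def test_exposure_plan_invariance(self, flat_scene, instrument, plan, flat_reflectance):
        """Rescaling exposures per channel leaves the recovery unchanged as
        long as all three cubes share the plan."""
        rng = np.random.default_rng(0)
        scaled = sim.ExposurePlan(plan.grid, plan.t_exp_s * rng.uniform(0.3, 0.9, len(plan.grid)))
        refl2 = cal.reflectance_transform(acquire_triple(flat_scene, instrument, scaled))
        np.testing.assert_allclose(refl2.data, flat_reflectance.data, atol=1e-12)


class TestValidityMask:
    def test_midrange_counts_all_valid(self):
        grid = build_wavelength_grid(500, 520, 5)
        c = np.full((3, 3, 5), 5000.0)
        assert cal.make_validity_mask(small_calset(c, c * 2, c * 0, grid)).all()

    def test_single_saturated_entry_flagged(self):
        grid = build_wavelength_grid(500, 520, 5)
        scene = np.full((3, 3, 5), 5000.0)
        scene[2, 1, 4] = 2**14 - 1
        mask = cal.make_validity_mask(small_calset(scene, np.full((3, 3, 5), 8000.0), np.zeros((3, 3, 5)), grid))
        assert not mask[2, 1, 4]
        assert mask.sum() == mask.size - 1

    def test_overexposed_bright_fraction_matches_injection(self):
        grid = build_wavelength_grid(500, 520, 5)
        rng = np.random.default_rng(7)
        bright = np.full((20, 20, 5), 8000.0)
        inject = rng.random((20, 20, 5)) < 0.15
        bright[inject] = 2**14 - 1
        mask = cal.make_validity_mask(
            small_calset(np.full((20, 20, 5), 4000.0), bright, np.zeros((20, 20, 5)), grid)
        )
        assert (~mask).sum() == inject.sum()


class TestSmoothing:
    def _refl(self, data, grid):
        cube = Hypercube(data, grid, "reflectance")
        return cal.ReflectanceCube(cube, np.ones(data.shape, dtype=bool))

    def test_constant_spectrum_unchanged(self, grid63):
        refl = self._refl(np.full((3, 3, 63), 0.2), grid63)
        out = cal.smooth_spectra(refl)
        np.testing.assert_allclose(out.data, 0.2, atol=1e-12)

    def test_quadratic_spectrum_reproduced(self, grid63):
        x = np.linspace(-1, 1, 63)
        spec = 0.3 + 0.1 * x + 0.05 * x**2
        refl = self._refl(np.tile(spec, (2, 2, 1)), grid63)
        out = cal.smooth_spectra(refl, poly_order=2, window_channels=9)
        np.testing.assert_allclose(out.data, refl.data, atol=1e-12)

    def test_noise_variance_reduced_by_coefficient_norm(self, grid63):
        """White-noise variance shrinks by the sum of squared SG weights."""
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.01, (40, 40, 63))
        out = cal.smooth_spectra(self._refl(0.3 + noise, grid63))
        interior = out.data[:, :, 10:-10] - 0.3
        factor = np.sum(savgol_coeffs(9, 2) ** 2)
        assert interior.var() == pytest.approx(factor * 1e-4, rel=0.05)
        assert interior.var() < noise[:, :, 10:-10].var()

    def test_preserves_grid_and_shape(self, grid63):
        refl = self._refl(np.random.default_rng(0).random((4, 5, 63)), grid63)
        out = cal.smooth_spectra(refl)
        assert out.shape == refl.shape
        assert out.grid == grid63

    def test_invalid_pixels_left_untouched(self, grid63):
        data = np.random.default_rng(1).random((3, 3, 63))
        refl = self._refl(data, grid63)
        refl.valid[1, 1, 5] = False
        out = cal.smooth_spectra(refl)
        np.testing.assert_array_equal(out.data[1, 1], data[1, 1])
        assert not out.valid[1, 1, 5]

    @pytest.mark.parametrize("window,order", [(8, 2), (3, 4), (65, 2)])
    def test_bad_window_rejected(self, grid63, window, order):
        refl = self._refl(np.zeros((2, 2, 63)), grid63)
        with pytest.raises(ValueError):
            cal.smooth_spectra(refl, poly_order=order, window_channels=window)
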