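"""Unit and property tests for the TIE solver and ROI phase integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tiettd import (
    DefocusPair,
    OpticalConfig,
    PhaseMap,
    RoiSet,
    bead_phase_map,
    equalize_pair,
    forward_tie_pair,
    gaussian_phase,
    roi_integrated_phase,
    solve_tie,
    sphere_volume,
)


def _pair(bf1, bf2, config):
    return DefocusPair(bf_over=bf1, bf_under=bf2, config=config)


class TestEqualizePair:
    def test_constant_images_meet_at_average(self, config):
        out = equalize_pair(
            _pair(np.full((8, 8), 100.0), np.full((8, 8), 102.0), config)
        )
        assert np.allclose(out.bf_over, 101.0)
        assert np.allclose(out.bf_under, 101.0)

    def test_identical_images_unchanged(self, config):
        img = np.random.default_rng(0).uniform(500, 1500, (16, 16))
        out = equalize_pair(_pair(img, img.copy(), config))
        np.testing.assert_array_equal(out.bf_over, img)
        np.testing.assert_array_equal(out.bf_under, img)

    def test_output_means_equal_average_of_input_means(self, config):
        rng = np.random.default_rng(42)
        bf1 = rng.uniform(900, 1100, (32, 32))
        bf2 = rng.uniform(900, 1100, (32, 32))
        bf1 += 980.2 - bf1.mean()
        bf2 += 1013.7 - bf2.mean()
        out = equalize_pair(_pair(bf1, bf2, config))
        assert out.bf_over.mean() == pytest.approx(996.95, abs=1e-9)
        assert out.bf_under.mean() == pytest.approx(996.95, abs=1e-9)

    def test_input_not_modified(self, config):
        bf1 = np.full((4, 4), 100.0)
        bf2 = np.full((4, 4), 110.0)
        pair = _pair(bf1.copy(), bf2.copy(), config)
        equalize_pair(pair)
        np.testing.assert_array_equal(pair.bf_over, bf1)
        np.testing.assert_array_equal(pair.bf_under, bf2)

    def test_shape_mismatch_rejected(self, config):
        with pytest.raises(ValueError, match="shapes differ"):
            _pair(np.zeros((4, 4)), np.zeros((4, 5)), config)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        imgs=hnp.arrays(
            float,
            (2, 8, 8),
            elements=st.floats(1.0, 1e4, allow_nan=False),
        )
    )
    def test_means_always_equalized_and_sum_preserved(self, imgs):
        config = OpticalConfig(wavelength=0.5)
        out = equalize_pair(_pair(imgs[0], imgs[1], config))
        target = 0.5 * (imgs[0].mean() + imgs[1].mean())
        assert out.bf_over.mean() == pytest.approx(target, rel=1e-12)
        assert out.bf_under.mean() == pytest.approx(target, rel=1e-12)
        np.testing.assert_allclose(
            out.bf_over + out.bf_under, imgs[0] + imgs[1], rtol=1e-12
        )


class TestSolveTie:
    def test_uniform_pair_gives_zero_phase(self, config):
        T = solve_tie(_pair(np.full((64, 64), 1000.0), np.full((64, 64), 1000.0), config))
        assert np.allclose(T.values, 0.0)

    def test_forward_inverse_round_trip(self, config):
        phase = gaussian_phase(1.0, sigma_um=3.0, pixel_size=config.pixel_size)
        pair = forward_tie_pair(phase, 1000.0, config)
        T = solve_tie(pair, regularization=0.0)
        expected = phase.values[1:-1, 1:-1]
        expected = expected - expected.mean()
        err = np.linalg.norm(T.values - expected) / np.linalg.norm(expected)
        assert err < 1e-6

    def test_constant_offset_on_one_image_is_removed(self, config):
        phase = gaussian_phase(0.5, sigma_um=4.0, pixel_size=config.pixel_size)
        pair = forward_tie_pair(phase, 1000.0, config)
        shifted = DefocusPair(
            bf_over=pair.bf_over + 50.0, bf_under=pair.bf_under, config=config
        )
        T0 = solve_tie(pair, 0.0)
        T1 = solve_tie(shifted, 0.0)
        # equalization removes the offset from the intensity difference exactly;
        # only the mean-intensity denominator shifts, by 25/1025 here
        err = np.linalg.norm(T1.values - T0.values) / np.linalg.norm(T0.values)
        assert err < 0.03

    def test_linearity_in_intensity_difference(self, config):
        phase = gaussian_phase(0.8, sigma_um=5.0, pixel_size=config.pixel_size)
        pair = forward_tie_pair(phase, 1000.0, config)
        mean = 0.5 * (pair.bf_over + pair.bf_under)
        half_diff = 0.5 * (pair.bf_over - pair.bf_under)
        a = 0.35
        scaled = DefocusPair(
            bf_over=mean + a * half_diff, bf_under=mean - a * half_diff, config=config
        )
        T = solve_tie(pair, 0.0)
        Ta = solve_tie(scaled, 0.0)
        np.testing.assert_allclose(Ta.values, a * T.values, rtol=1e-10, atol=1e-12)

    def test_independent_of_mounting_medium_index(self, config):
        phase = gaussian_phase(1.0, sigma_um=3.0, pixel_size=config.pixel_size)
        pair = forward_tie_pair(phase, 1000.0, config)
        other = OpticalConfig(
            wavelength=config.wavelength,
            n_imm=config.n_imm,
            n_medium=1.41,
            defocus_separation=config.defocus_separation,
            pixel_size=config.pixel_size,
        )
        T0 = solve_tie(pair, 1e-3)
        T1 = solve_tie(DefocusPair(pair.bf_over, pair.bf_under, other), 1e-3)
        np.testing.assert_array_equal(T0.values, T1.values)

    def test_dark_level_subtracted_before_solving(self, config):
        phase = gaussian_phase(1.0, sigma_um=3.0, pixel_size=config.pixel_size)
        pair = forward_tie_pair(phase, 1000.0, config)
        dark_cfg = OpticalConfig(
            wavelength=config.wavelength,
            n_imm=config.n_imm,
            defocus_separation=config.defocus_separation,
            pixel_size=config.pixel_size,
            dark_level=100.0,
        )
        raised = DefocusPair(pair.bf_over + 100.0, pair.bf_under + 100.0, dark_cfg)
        np.testing.assert_allclose(
            solve_tie(raised, 0.0).values, solve_tie(pair, 0.0).values, atol=1e-12
        )

    def test_output_is_zero_mean_and_two_pixels_smaller(self, config):
        phase = gaussian_phase(1.0, sigma_um=3.0, pixel_size=config.pixel_size)
        T = solve_tie(forward_tie_pair(phase, 1000.0, config), 1e-3)
        assert T.values.shape == (254, 254)
        assert abs(T.values.mean()) < 1e-12

    def test_negative_regularization_rejected(self, config):
        pair = _pair(np.full((16, 16), 10.0), np.full((16, 16), 10.0), config)
        with pytest.raises(ValueError, match="regularization"):
            solve_tie(pair, -1e-3)

    def test_non_positive_intensity_rejected(self, config):
        pair = _pair(np.full((16, 16), -5.0), np.full((16, 16), -5.0), config)
        with pytest.raises(ValueError, match="degenerate"):
            solve_tie(pair)


class TestRoiIntegratedPhase:
    def test_zero_and_constant_fields_integrate_to_zero(self, make_disk_labels, config):
        rois = make_disk_labels((64, 64), 5.0, config.pixel_size)
        for value in (0.0, 3.7):
            T = PhaseMap(np.full((64, 64), value), config.pixel_size)
            table = roi_integrated_phase(T, rois)
            assert table.integral_T.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_gauge_invariance_under_constant_offset(self, make_disk_labels, config):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(64, 64))
        rois = make_disk_labels((64, 64), 5.0, config.pixel_size)
        t0 = roi_integrated_phase(PhaseMap(values, config.pixel_size), rois)
        t1 = roi_integrated_phase(PhaseMap(values + 12.3, config.pixel_size), rois)
        assert t1.integral_T.iloc[0] == pytest.approx(t0.integral_T.iloc[0], abs=1e-8)

    def test_bead_integral_matches_analytic_sphere(self, config):
        diameter, delta_n = 7.7, 0.05
        phase = bead_phase_map(diameter, delta_n, config.wavelength, config.pixel_size)
        ny, nx = phase.values.shape
        yy, xx = np.indices((ny, nx))
        r = np.hypot(yy - (ny - 1) / 2, xx - (nx - 1) / 2) * config.pixel_size
        rois = RoiSet(np.where(r <= 6.0, 1, 0))
        table = roi_integrated_phase(phase, rois)
        expected = (2 * np.pi / config.wavelength) * delta_n * sphere_volume(diameter)
        assert table.integral_T.iloc[0] == pytest.approx(expected, rel=0.02)

    def test_empty_background_is_an_error(self, config):
        T = PhaseMap(np.zeros((8, 8)), config.pixel_size)
        rois = RoiSet(np.ones((8, 8), dtype=int))
        with pytest.raises(ValueError, match="background"):
            roi_integrated_phase(T, rois)

    def test_shape_mismatch_rejected(self, make_disk_labels, config):
        T = PhaseMap(np.zeros((8, 8)), config.pixel_size)
        rois = make_disk_labels((9, 9), 1.0, config.pixel_size)
        with pytest.raises(ValueError, match="shape"):
            roi_integrated_phase(T, rois)
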