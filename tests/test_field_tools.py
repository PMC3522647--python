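"""B0 mapping, shimming and field statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiot2star import (FieldMap, ImageGeometry, compute_b0_map,
                          dispersion_per_voxel, field_stats, fit_shim,
                          simulate_phase_images)
from cardiot2star.errors import ValidationError


@pytest.fixture(scope="module")
def unit_geom():
    # 1 mm isotropic grid for arithmetic-friendly coordinates
    return ImageGeometry(matrix=(80, 80), fov_mm=(80.0, 80.0))


class TestB0Map:
    def test_quarter_cycle_phase_difference(self):
        p1 = np.zeros((4, 4))
        p2 = np.full((4, 4), np.pi / 2)
        fm = compute_b0_map(p1, p2, 2.04, 3.06)
        assert fm.dfreq_hz[0, 0] == pytest.approx((np.pi / 2) / (2 * np.pi * 1.02e-3))

    def test_equal_phases_zero_field(self):
        p = np.random.default_rng(0).uniform(-np.pi, np.pi, (6, 6))
        fm = compute_b0_map(p, p.copy(), 2.04, 3.06)
        assert np.allclose(fm.dfreq_hz, 0)

    def test_beyond_nyquist_aliases(self):
        true_hz = 600.0
        p1, p2 = simulate_phase_images(np.full((3, 3), true_hz), 2.04, 3.06)
        fm = compute_b0_map(p1, p2, 2.04, 3.06)
        nyq = 1e3 / 1.02  # full wrap period in Hz
        assert fm.dfreq_hz[0, 0] == pytest.approx(true_hz - nyq, abs=1e-6)
        assert fm.nyquist_hz == pytest.approx(490.196, abs=0.001)

    def test_equal_echo_times_rejected(self):
        with pytest.raises(ValidationError):
            compute_b0_map(np.zeros((2, 2)), np.zeros((2, 2)), 2.04, 2.04)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(df=st.floats(-480.0, 480.0))
    def test_roundtrip_identity_below_nyquist(self, df):
        p1, p2 = simulate_phase_images(np.full((2, 2), df), 2.04, 3.06)
        fm = compute_b0_map(p1, p2, 2.04, 3.06)
        assert fm.dfreq_hz[0, 0] == pytest.approx(df, abs=1e-9)


class TestShim:
    def test_linear_field_fully_removed_at_order_1(self, unit_geom):
        y, x = unit_geom.coordinate_grids()
        fm = FieldMap(3.0 * x - 2.0 * y + 7.0, np.ones(unit_geom.shape, bool),
                      1.02, unit_geom)
        roi = np.hypot(y, x) <= 30
        sol = fit_shim(fm, roi, order=1)
        assert sol.post_stats["peak_to_peak_hz"] < 1e-9
        assert sol.coefficients["x"] == pytest.approx(3.0)
        assert sol.coefficients["y"] == pytest.approx(-2.0)

    def test_second_order_coefficient_recovered(self, unit_geom):
        y, x = unit_geom.coordinate_grids()
        fm = FieldMap(5.0 * (x**2 - y**2), np.ones(unit_geom.shape, bool),
                      1.02, unit_geom)
        roi = np.hypot(y, x) <= 30
        sol = fit_shim(fm, roi, order=2)
        assert sol.coefficients["x2-y2"] == pytest.approx(5.0)
        assert sol.post_stats["rms_hz"] < 1e-8

    def test_constant_field_has_zero_gradient_terms(self, unit_geom):
        fm = FieldMap(np.full(unit_geom.shape, 120.0),
                      np.ones(unit_geom.shape, bool), 1.02, unit_geom)
        sol = fit_shim(fm, np.ones(unit_geom.shape, bool), order=2)
        for name, val in sol.coefficients.items():
            if name != "const":
                assert val == pytest.approx(0.0, abs=1e-9)

    def test_shim_never_increases_roi_rms(self, unit_geom):
        rng = np.random.default_rng(4)
        fm = FieldMap(rng.normal(0, 50, unit_geom.shape),
                      np.ones(unit_geom.shape, bool), 1.02, unit_geom)
        roi = np.zeros(unit_geom.shape, bool)
        roi[20:60, 15:70] = True
        for order in (1, 2):
            sol = fit_shim(fm, roi, order=order)
            assert sol.post_stats["rms_hz"] <= sol.pre_stats["rms_hz"] + 1e-12

    def test_roi_smaller_than_basis_rejected(self, unit_geom):
        fm = FieldMap(np.zeros(unit_geom.shape), np.ones(unit_geom.shape, bool),
                      1.02, unit_geom)
        roi = np.zeros(unit_geom.shape, bool)
        roi[0, :3] = True
        with pytest.raises(ValidationError):
            fit_shim(fm, roi, order=2)


class TestFieldStats:
    def test_constant_field(self, unit_geom):
        fm = FieldMap(np.full(unit_geom.shape, 42.0),
                      np.ones(unit_geom.shape, bool), 1.02, unit_geom)
        st_ = field_stats(fm, np.ones(unit_geom.shape, bool))
        assert st_["peak_to_peak_hz"] == 0.0
        assert st_["fwhm_hz"] == 0.0

    def test_linear_ramp_statistics(self, unit_geom):
        y, x = unit_geom.coordinate_grids()
        fm = FieldMap(3.0 * x, np.ones(unit_geom.shape, bool), 1.02, unit_geom)
        roi = (np.abs(x) <= 20) & (np.abs(y) <= 20)  # 40 mm wide ROI
        st_ = field_stats(fm, roi)
        assert st_["peak_to_peak_hz"] == pytest.approx(120.0, abs=3.1)  # 3 Hz/mm x 40 mm
        assert st_["mean_gradient_hz_per_mm"] == pytest.approx(3.0, abs=1e-9)

    def test_gaussian_fwhm(self, unit_geom):
        rng = np.random.default_rng(9)
        sigma = 80.0
        fm = FieldMap(rng.normal(0, sigma, unit_geom.shape),
                      np.ones(unit_geom.shape, bool), 1.02, unit_geom)
        st_ = field_stats(fm, np.ones(unit_geom.shape, bool))
        assert st_["fwhm_hz"] == pytest.approx(2.355 * sigma, rel=0.12)

    def test_single_voxel_roi_flags_gradients(self, unit_geom):
        fm = FieldMap(np.zeros(unit_geom.shape), np.ones(unit_geom.shape, bool),
                      1.02, unit_geom)
        roi = np.zeros(unit_geom.shape, bool)
        roi[5, 5] = True
        st_ = field_stats(fm, roi)
        assert np.isnan(st_["max_gradient_hz_per_mm"])
        assert "flag" in st_["gradient_flag"] or st_["gradient_flag"]


class TestDispersion:
    @pytest.mark.parametrize("grad,extent,expected", [
        (3.0, 4.0, 12.0),    # ventricular mean gradient, 4 mm slice
        (20.0, 4.0, 80.0),   # epicardial gradient, 4 mm slice
        (2.0, 1.0, 2.0),     # 80 Hz over 40 mm expressed per mm
    ])
    def test_products(self, grad, extent, expected):
        assert dispersion_per_voxel(grad, extent) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            dispersion_per_voxel(-1.0, 4.0)
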