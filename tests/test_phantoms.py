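"""Phantom generators: geometry, ground-truth bookkeeping, motion model."""

import numpy as np
import pytest

from cardiot2star import (HeartPhantomSpec, ImageGeometry, make_heart_phantom,
                          make_long_t2star_phantom, make_medium_t2star_phantom,
                          perturb_breath_holds)
from cardiot2star.errors import ValidationError


class TestLongPhantom:
    def test_capillary_is_signal_void(self):
        tm = make_long_t2star_phantom()
        cap = tm.meta["capillary_mask"]
        assert cap.any()
        assert np.all(tm.s0[cap] == 0)

    def test_dipole_falls_off_as_inverse_square(self):
        tm = make_long_t2star_phantom(dipole_amplitude_hz_mm2=100.0)
        # evaluate the dipole on-axis (theta = 0 from capillary center) at r, 2r
        cy, cx = -30.0, 0.0
        y, x = tm.geometry.coordinate_grids()
        dy, dx = tm.geometry.resolution_mm

        def field_at(off_mm):
            j = np.argmin(np.abs(x[0] - (cx + off_mm)))
            i = np.argmin(np.abs(y[:, 0] - cy))
            return tm.dfreq_hz[i, j]

        f1, f2 = field_at(8.0), field_at(16.0)
        assert f1 / f2 == pytest.approx(4.0, rel=0.15)  # discretized 1/r^2

    def test_perturbation_off_gives_flat_field(self):
        tm = make_long_t2star_phantom(dipole_amplitude_hz_mm2=0.0)
        assert np.all(tm.dfreq_hz == 0)

    def test_inclusion_outside_cylinder_rejected(self):
        with pytest.raises(ValidationError):
            make_long_t2star_phantom(tube_center_mm=(80.0, 0.0))


class TestMediumPhantom:
    def test_uniform_t2star(self):
        tm = make_medium_t2star_phantom()
        assert np.all(tm.t2star_ms[tm.object_mask()] == 20.0)

    def test_diameter_in_voxels(self):
        g = ImageGeometry(matrix=(120, 120), fov_mm=(120.0, 120.0))
        tm = make_medium_t2star_phantom(geometry=g)
        # 80 mm / 1 mm resolution -> widest row spans ~80 voxels
        widths = tm.object_mask().sum(axis=1)
        assert widths.max() == pytest.approx(80, abs=1)

    def test_nonpositive_t2star_rejected(self):
        with pytest.raises(ValidationError):
            make_medium_t2star_phantom(t2star_ms=0.0)


class TestHeartPhantom:
    def test_default_modulation_is_27_percent(self, heart_phantom):
        t2 = heart_phantom.meta["segment_t2star_by_frame"]
        pct = (t2.max(axis=0) - t2.min(axis=0)) / t2.min(axis=0)
        assert np.allclose(pct, 0.27, atol=1e-9)

    def test_zero_amplitude_constant_over_cycle(self):
        spec = HeartPhantomSpec(cyclic_amplitude=0.0, n_phases=6)
        tm = make_heart_phantom(spec)
        t2 = tm.meta["segment_t2star_by_frame"]
        assert np.allclose(t2, t2[0])

    def test_minimum_at_end_systole_maximum_in_diastole(self, heart_phantom):
        t2 = heart_phantom.meta["segment_t2star_by_frame"]
        u = heart_phantom.meta["phase_fractions"]
        spec = heart_phantom.meta["spec"]
        es = heart_phantom.meta["es_frame"]
        for s in range(6):
            assert u[t2[:, s].argmin()] == pytest.approx(spec.end_systole_fraction, abs=0.05)
            assert u[t2[:, s].argmax()] == pytest.approx(spec.t2star_peak_fraction, abs=0.05)
            assert t2[es, s] == pytest.approx(spec.segment_t2star_es_ms[s], abs=1e-9)

    def test_systolic_wall_thicker_than_diastolic(self, heart_phantom):
        m = heart_phantom.meta
        es = m["es_frame"]
        wall_ed = m["epi_radius_mm"][0] - m["endo_radius_mm"][0]
        wall_es = m["epi_radius_mm"][es] - m["endo_radius_mm"][es]
        assert wall_es > wall_ed

    def test_myocardial_area_conserved_over_cycle(self, heart_phantom):
        areas = heart_phantom.meta["myocardium_masks"].sum(axis=(1, 2))
        assert areas.max() - areas.min() <= 0.05 * areas.mean()

    def test_segment_labels_round_trip_with_analysis(self, heart_phantom):
        from cardiot2star.segment_analysis import aha_segments
        m = heart_phantom.meta
        k = m["es_frame"]
        lab = aha_segments(m["myocardium_masks"][k], m["center"],
                           m["spec"].insertion_angle_deg)
        assert np.array_equal(lab.labels, m["segment_labels"][k])

    def test_needs_at_least_two_phases(self):
        with pytest.raises(ValidationError):
            HeartPhantomSpec(n_phases=1)

    def test_explicit_thinner_systolic_wall_rejected(self):
        with pytest.raises(ValidationError):
            HeartPhantomSpec(endo_radius_es_mm=21.0, epi_radius_es_mm=27.0)


class TestBreathHoldPerturbation:
    def test_zero_magnitudes_identity(self, heart_phantom):
        maps, transforms = perturb_breath_holds(heart_phantom, 3, 0.0, 0.0, seed=1)
        for m, t in zip(maps, transforms):
            assert np.array_equal(m.s0, heart_phantom.s0)
            assert t.max_displacement(heart_phantom.geometry.shape) == 0.0

    def test_seed_reproducible(self, heart_phantom):
        _, t1 = perturb_breath_holds(heart_phantom, 3, seed=11)
        _, t2 = perturb_breath_holds(heart_phantom, 3, seed=11)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.linear, b.linear)
            assert np.array_equal(a.translation, b.translation)

    def test_recorded_transform_matches_applied_shift(self, medium_small):
        from cardiot2star.registration import AffineTransform2D, apply_transform
        maps, transforms = perturb_breath_holds(medium_small, 1, 2.0, 0.0, seed=3)
        t = transforms[0]
        # re-applying the recorded transform to the original reproduces the copy
        expected = apply_transform(medium_small.s0, t)
        assert np.allclose(maps[0].s0, expected, atol=1e-9)
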