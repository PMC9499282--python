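import math

import numpy as np
import pytest

import stereodepth as sd
from stereodepth.first_order import gabor_field


def brute_force_energy(unit, window, cl, cr):
    """Independent per-pixel oracle: explicit double loops over the lattice."""
    total = 0.0
    for parity in ("even", "odd"):
        s = 0.0
        for eye, img in (("left", cl), ("right", cr)):
            p = unit.monocular_params(eye, parity)
            f = p.spatial_frequency / 60.0
            for i, y in enumerate(window.y):
                for j, x in enumerate(window.x):
                    w = (p.amplitude
                         * math.exp(-((x - p.centre[0])**2 + (y - p.centre[1])**2)
                                    / (2 * p.envelope_sd**2))
                         * math.cos(2 * math.pi * f * (x - p.centre[0]) + p.phase))
                    s += w * img[i, j]
        total += s**2
    return total


class TestReceptiveFields:
    def test_odd_field_weights_sum_to_zero(self):
        unit = sd.build_quadrature_unit(spatial_frequency=4.0)
        w = sd.Window(centre=(0.0, 0.0), shape=(41, 41), pixel_pitch=1.0)
        odd = gabor_field(unit.monocular_params("left", "odd"), w)
        assert abs(odd.sum()) < 1e-10 * np.abs(odd).sum()

    def test_zero_disparity_gives_identical_eyes(self):
        unit = sd.build_quadrature_unit(position_disparity=0.0, phase_disparity=0.0)
        w = sd.Window(centre=(0.0, 0.0), shape=(33, 33), pixel_pitch=1.9)
        flds = unit.sample_fields(w)
        np.testing.assert_array_equal(flds[("left", "even")], flds[("right", "even")])
        np.testing.assert_array_equal(flds[("left", "odd")], flds[("right", "odd")])

    def test_position_disparity_translates_right_field(self):
        # on a 1-arcmin lattice a 10-arcmin offset is an exact 10-pixel shift
        unit = sd.build_quadrature_unit(position_disparity=10.0)
        w = sd.Window(centre=(0.0, 0.0), shape=(61, 61), pixel_pitch=1.0)
        flds = unit.sample_fields(w)
        left, right = flds[("left", "even")], flds[("right", "even")]
        np.testing.assert_allclose(right[:, :-10], left[:, 10:], atol=1e-12)

    def test_sub_pixel_envelope_rejected(self):
        unit = sd.build_quadrature_unit(envelope_sd=0.5)
        w = sd.Window(centre=(0.0, 0.0), shape=(33, 33), pixel_pitch=1.9)
        with pytest.raises(ValueError, match="resolved"):
            unit.sample_fields(w)


class TestEnergyResponse:
    def test_blank_frame_gives_zero(self, toy_window):
        unit = sd.build_quadrature_unit()
        blank = np.zeros(toy_window.shape)
        assert sd.energy_response(unit, blank, blank, toy_window) == 0.0

    def test_linearity_and_quadratic_scaling(self, toy_window, toy_frames):
        unit = sd.build_quadrature_unit()
        flds = unit.sample_fields(toy_window)
        cl, cr = toy_frames
        s1 = sd.simple_response(flds[("left", "even")], flds[("right", "even")], cl, cr)
        s2 = sd.simple_response(flds[("left", "even")], flds[("right", "even")],
                                2 * cl, 2 * cr)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)
        e1 = sd.energy_response(flds, cl, cr)
        e3 = sd.energy_response(flds, 3 * cl, 3 * cr)
        assert e3 == pytest.approx(9 * e1, rel=1e-12)

    def test_both_eye_polarity_flip_invariance(self, toy_window, toy_frames):
        unit = sd.build_quadrature_unit(position_disparity=6.0)
        flds = unit.sample_fields(toy_window)
        cl, cr = toy_frames
        assert sd.energy_response(flds, cl, cr) == pytest.approx(
            sd.energy_response(flds, -cl, -cr), rel=1e-14)

    def test_matches_brute_force_oracle(self, toy_window, toy_frames):
        unit = sd.build_quadrature_unit(spatial_frequency=6.0, envelope_sd=6.0,
                                        position_disparity=4.0)
        cl, cr = toy_frames
        fast = sd.energy_response(unit, cl, cr, toy_window)
        slow = brute_force_energy(unit, toy_window, cl, cr)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_lattice_mismatch_rejected(self, toy_window):
        unit = sd.build_quadrature_unit()
        flds = unit.sample_fields(toy_window)
        with pytest.raises(ValueError, match="lattice"):
            sd.simple_response(flds[("left", "even")], flds[("right", "even")],
                               np.zeros((8, 8)), np.zeros((8, 8)))


class TestTuningCurve:
    def test_requires_two_frames(self, circle_spec):
        unit = sd.build_quadrature_unit()
        with pytest.raises(ValueError, match="n_frames"):
            sd.tuning_curve(unit, circle_spec, n_frames=1, rng=0)

    def test_single_point_grid_is_its_own_argmax(self, circle_spec):
        unit = sd.build_quadrature_unit(position_disparity=10.0)
        c = sd.tuning_curve(unit, circle_spec, np.array([10.0]), n_frames=5,
                            rng=0, correlations="correlated")
        assert c.preferred_disparity == 10.0

    def test_peak_at_encoded_disparity(self, circle_spec):
        unit = sd.build_quadrature_unit(spatial_frequency=4.0, position_disparity=10.0)
        c = sd.tuning_curve(unit, circle_spec, np.arange(-20.0, 21.0), n_frames=150,
                            rng=2, correlations="correlated")
        assert abs(c.preferred_disparity - 10.0) <= 1.0

    def test_methods_agree_on_peak_location(self, circle_spec):
        unit = sd.build_quadrature_unit(spatial_frequency=4.0, position_disparity=8.0)
        probes = np.arange(-16.0, 17.0, 2.0)
        fast = sd.tuning_curve(unit, circle_spec, probes, n_frames=60, rng=3,
                               correlations="correlated")
        slow = sd.tuning_curve(unit, circle_spec, probes, n_frames=60, rng=3,
                               correlations="correlated", method="rerender")
        assert abs(fast.preferred_disparity - slow.preferred_disparity) <= 2.0

    def test_unit_outside_target_region_rejected(self, circle_spec):
        unit = sd.build_quadrature_unit(centre=(170.0, 0.0))   # in the annulus
        with pytest.raises(ValueError, match="target region"):
            sd.tuning_curve(unit, circle_spec, n_frames=5, rng=0)

    def test_side_lobe_spacing_scales_inversely_with_frequency(self):
        # fine dots so the curve's periodicity reflects the filters, not
        # the 9-arcmin dot profile
        spec = sd.preset("exp1_circle", dot_size=2.0, pixel_pitch=0.95)
        trough = {}
        for f in (4.0, 8.0):
            unit = sd.build_quadrature_unit(spatial_frequency=f,
                                            position_disparity=0.0)
            probes = np.arange(0.0, 24.01, 0.5)
            c = sd.tuning_curve(unit, spec, probes, n_frames=300, rng=11,
                                correlations="correlated")
            limit = int(1.5 * 60.0 / f / 0.5)
            trough[f] = probes[int(np.argmin(c.mean_response[:limit]))]
        ratio = trough[4.0] / trough[8.0]
        assert ratio == pytest.approx(2.0, rel=0.10)
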