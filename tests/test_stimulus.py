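import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stereodepth as sd
from stereodepth.stimulus import (
    RegionGeometry,
    default_canvas,
    dot_count,
    frames_for_duration,
)


class TestDotCount:
    def test_coverage_rule_rounds_then_evens(self):
        # 0.25 * 10000 / 81 = 30.86 -> 31 -> 30 after evening
        assert dot_count(100.0 * 100.0, 9.0, 0.25) == 30

    def test_vanishing_coverage_gives_empty_field(self):
        assert dot_count(100.0 * 100.0, 9.0, 1e-9) == 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dot_count(100.0, -1.0, 0.25)
        with pytest.raises(ValueError):
            dot_count(0.0, 9.0, 0.25)
        with pytest.raises(ValueError):
            dot_count(100.0, 9.0, 1.5)

    @given(coverage=st.floats(0.05, 1.0), config=st.sampled_from(["circle", "edge"]),
           region=st.sampled_from(["target", "reference"]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_realised_coverage_within_rounding_error(self, coverage, config, region):
        # rounding contributes up to half a dot-area, evening up to one more
        geom = RegionGeometry.for_configuration(config)
        area = geom.area(region)
        n = dot_count(area, 9.0, coverage)
        assert abs(n * 81.0 / area - coverage) <= 1.5 * 81.0 / area + 1e-12


class TestDotField:
    def test_equal_bright_and_dark_counts(self, rng):
        geom = RegionGeometry.for_configuration("circle")
        for region in ("target", "reference"):
            field = sd.make_dot_field(geom, region, 9.0, 0.25, rng)
            assert (field.polarities == 1).sum() == (field.polarities == -1).sum()

    def test_positions_inside_region(self, rng):
        geom = RegionGeometry.for_configuration("circle")
        field = sd.make_dot_field(geom, "reference", 9.0, 0.25, rng)
        assert geom.contains("reference", field.positions).all()


class TestDisparity:
    def test_zero_disparity_is_identity(self, rng, circle_spec):
        dots = sd.full_dot_field(circle_spec, rng)
        left, right = sd.apply_disparity(dots, 0.0)
        np.testing.assert_array_equal(left.positions, right.positions)
        np.testing.assert_array_equal(left.positions, dots.positions)

    def test_symmetric_split_shifts_half_each_eye(self, rng, circle_spec):
        dots = sd.full_dot_field(circle_spec, rng)
        left, right = sd.apply_disparity(dots, 28.0, 0.5)
        t = dots.is_target
        np.testing.assert_allclose(left.positions[t, 0] - dots.positions[t, 0], 14.0)
        np.testing.assert_allclose(right.positions[t, 0] - dots.positions[t, 0], -14.0)
        # inter-ocular difference is the full disparity; reference untouched
        np.testing.assert_allclose(left.positions[t, 0] - right.positions[t, 0], 28.0)
        np.testing.assert_array_equal(left.positions[~t], right.positions[~t])

    def test_disparity_is_invertible(self, rng, circle_spec):
        dots = sd.full_dot_field(circle_spec, rng)
        left, _ = sd.apply_disparity(dots, 28.0)
        back, _ = sd.apply_disparity(left, -28.0)
        np.testing.assert_allclose(back.positions, dots.positions)


class TestAnticorrelate:
    def test_involution(self, rng, circle_spec):
        dots = sd.full_dot_field(circle_spec, rng)
        left, right = sd.apply_disparity(dots, 28.0)
        l1, r1 = sd.anticorrelate(left, right)
        l2, r2 = sd.anticorrelate(l1, r1)
        np.testing.assert_array_equal(r2.polarities, right.polarities)
        np.testing.assert_array_equal(l2.polarities, left.polarities)

    def test_polarity_products(self, rng, circle_spec):
        dots = sd.full_dot_field(circle_spec, rng)
        left, right = sd.apply_disparity(dots, 28.0)
        l1, r1 = sd.anticorrelate(left, right)
        t = dots.is_target
        assert (l1.polarities[t] * r1.polarities[t] == -1).all()
        assert (l1.polarities[~t] * r1.polarities[~t] == 1).all()


class TestRenderSequence:
    def test_duration_to_frame_counts(self):
        assert frames_for_duration(80.0) == 5
        assert frames_for_duration(700.0) == 42

    def test_frame_luminances_are_the_three_display_levels(self, circle_spec):
        seq = sd.render_sequence(circle_spec, seed=0)
        values = np.unique(seq.frames[0][0])
        assert set(values) <= {0.0, 13.5, 27.0}
        assert 13.5 in values

    def test_frames_independently_repositioned(self, circle_spec):
        seq = sd.render_sequence(circle_spec, seed=0)
        assert not np.array_equal(seq.frames[0][0], seq.frames[1][0])

    def test_seeded_rendering_is_bit_reproducible(self, circle_spec):
        a = sd.render_sequence(circle_spec, seed=7)
        b = sd.render_sequence(circle_spec, seed=7)
        for (l1, r1), (l2, r2) in zip(a.frames, b.frames):
            np.testing.assert_array_equal(l1, l2)
            np.testing.assert_array_equal(r1, r2)

    def test_masks_disjoint_and_match_printed_geometry(self, circle_spec):
        seq = sd.render_sequence(circle_spec, seed=0)
        assert not (seq.target_mask & seq.reference_mask).any()
        px_area = circle_spec.pixel_pitch**2
        target_area = seq.target_mask.sum() * px_area
        ref_area = seq.reference_mask.sum() * px_area
        assert target_area == pytest.approx(np.pi * 138.0**2, rel=0.02)
        assert ref_area == pytest.approx(np.pi * (204.0**2 - 138.0**2), rel=0.02)

    def test_eccentric_stimulus_beyond_small_canvas_errors(self):
        spec = sd.preset("exp1_circle", eccentricity=12.7)
        small = default_canvas(sd.preset("exp1_circle", eccentricity=0.0))
        with pytest.raises(ValueError, match="canvas"):
            sd.render_sequence(spec, seed=0, window=small)

    def test_anticorrelated_target_flips_pixel_correlation(self):
        spec_c = sd.preset("exp1_circle", correlation="correlated",
                           target_disparity=0.0)
        spec_a = sd.preset("exp1_circle", correlation="anticorrelated",
                           target_disparity=0.0)
        corr = {}
        for name, spec in (("c", spec_c), ("a", spec_a)):
            seq = sd.render_sequence(spec, seed=3)
            l = sd.to_contrast(seq.frames[0][0], spec)
            r = sd.to_contrast(seq.frames[0][1], spec)
            m = seq.target_mask & (l != 0) & (r != 0)
            corr[name] = np.corrcoef(l[m], r[m])[0, 1]
            ref = seq.reference_mask & (l != 0) & (r != 0)
            # dots from the opposite region intrude across the boundary,
            # so the correlation is near, not exactly, +/-1
            assert np.corrcoef(l[ref], r[ref])[0, 1] > 0.9
        assert corr["c"] > 0.99
        assert corr["a"] < -0.9


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(coverage_fraction=0.0), dict(coverage_fraction=1.5),
        dict(dot_size=-1.0), dict(duration_frames=0),
        dict(configuration="square"), dict(meridian="up"),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.StimulusSpec(**kwargs)

    def test_presets_set_configuration_and_meridian(self):
        assert sd.preset("exp1_edge").configuration == "edge"
        assert sd.preset("exp2_edge").meridian == "vertical_below"
        with pytest.raises(KeyError):
            sd.preset("exp3_ring")

    def test_spec_json_round_trip(self, circle_spec):
        assert sd.StimulusSpec.from_json(circle_spec.to_json()) == circle_spec


def test_write_sequence_outputs_pngs_and_metadata(tmp_path, circle_spec):
    spec = sd.preset("exp1_circle", duration_ms=80)
    seq = sd.render_sequence(spec, seed=0)
    out = sd.write_sequence(seq, tmp_path / "stim")
    assert (out / "f0001_L.png").exists()
    assert (out / "f0005_R.png").exists()
    assert (out / "mask_target.png").exists()
    assert (out / "metadata.json").exists()
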