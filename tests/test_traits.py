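"""Trait extraction: golden values, invariants, brute-force agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croppainter.traits import (EmptyForegroundError, TraitSchema,
                                color_traits, extract_traits,
                                fractal_dimension, histogram_stats,
                                morphology_traits)


def colored(mask, color=(0, 200, 0)):
    rgb = np.zeros(mask.shape + (3,), dtype=np.uint8)
    rgb[mask] = color
    return rgb


class TestHistogramStats:
    @pytest.mark.parametrize("values,expected", [
        (np.full(100, 0.5), (0.5, 0.0, 0.0, 0.0, 1.0, 0.0)),
        (np.array([0.0] * 50 + [1.0] * 50), (0.5, 0.5, 0.2, 0.0, 0.5, 1.0)),
    ])
    def test_golden_examples(self, values, expected):
        result = histogram_stats(values, n_bins=256)
        assert result == pytest.approx(expected, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyForegroundError):
            histogram_stats([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            histogram_stats([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_within_bin_width(self, values):
        """M and SE agree with an unbinned pixel loop within 1/n_bins."""
        n_bins = 64
        m, se, *_ = histogram_stats(values, n_bins=n_bins)
        z = np.asarray(values)
        assert m == pytest.approx(z.mean(), abs=1.0 / n_bins)
        assert se == pytest.approx(z.std(), abs=1.0 / n_bins)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=100))
    @settings(max_examples=50, deadline=None)
    def test_distribution_statistics_bounds(self, values):
        m, se, s, mu3, u, e = histogram_stats(values)
        assert 0.0 <= m <= 1.0
        assert 0.0 < u <= 1.0
        assert e >= 0.0
        assert 0.0 <= s < 1.0


class TestMorphology:
    def test_full_square(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        tpa, h, w, cba, tbr, thr, p, par = morphology_traits(mask)
        assert (tpa, h, w, cba) == (100, 10, 10, 100)
        assert (tbr, thr) == (1.0, 1.0)
        assert (p, par) == (36, 0.36)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        tpa, h, w, cba, tbr, thr, p, par = morphology_traits(mask)
        assert (tpa, h, w, cba, tbr, thr, p, par) == (1, 1, 1, 1, 1, 1, 1, 1)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyForegroundError):
            morphology_traits(np.zeros((5, 5), dtype=bool))

    def test_border_touching_square_counts_border_as_background(self):
        mask = np.ones((4, 4), dtype=bool)
        tpa, h, w, cba, tbr, thr, p, par = morphology_traits(mask)
        assert tpa == 16
        assert p == 12  # all but the 2x2 interior


class TestFractalDimension:
    def test_filled_square_is_plane_like(self):
        assert fractal_dimension(np.ones((64, 64), dtype=bool)) \
            == pytest.approx(2.0, abs=0.1)

    def test_thin_line_is_curve_like(self):
        mask = np.zeros((3, 64), dtype=bool)
        mask[1] = True
        assert fractal_dimension(mask) == pytest.approx(1.0, abs=0.1)

    def test_single_pixel_degenerate(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert fractal_dimension(mask) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyForegroundError):
            fractal_dimension(np.zeros((4, 4), dtype=bool))

    def test_matches_brute_force_box_counts(self):
        """Slope re-derived from explicitly enumerated box counts."""
        rng = np.random.default_rng(0)
        mask = rng.random((40, 52)) > 0.6
        mask[0, 0] = True
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        side = 64
        box = np.zeros((side, side), dtype=bool)
        box[:crop.shape[0], :crop.shape[1]] = crop
        sizes, counts = [], []
        s = 1
        while s <= side // 2:
            count = 0
            for i in range(0, side, s):
                for j in range(0, side, s):
                    count += box[i:i + s, j:j + s].any()
            sizes.append(s)
            counts.append(count)
            s *= 2
        slope = np.polyfit(np.log(1.0 / np.array(sizes)),
                           np.log(counts), 1)[0]
        assert fractal_dimension(mask) == pytest.approx(slope, abs=1e-10)


class TestColorTraits:
    def test_pure_green_foreground(self):
        mask = np.ones((10, 10), dtype=bool)
        gpa, ypa, ytr = color_traits(colored(mask, (0, 255, 0)), mask)
        assert (gpa, ypa, ytr) == (100, 0, 100.0)

    def test_half_yellow_half_green(self):
        # hue 45 deg yellow: (255, 191, 0)
        mask = np.ones((10, 10), dtype=bool)
        rgb = colored(mask, (0, 255, 0))
        rgb[:5] = (255, 191, 0)
        gpa, ypa, ytr = color_traits(rgb, mask)
        assert (gpa, ypa, ytr) == (50, 50, 2.0)

    def test_desaturated_foreground_below_floor(self):
        mask = np.ones((6, 6), dtype=bool)
        gpa, ypa, ytr = color_traits(colored(mask, (30, 30, 30)), mask)
        assert (gpa, ypa) == (0, 0)
        assert ytr == 36.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            color_traits(np.zeros((4, 4, 3), dtype=np.uint8),
                         np.ones((5, 5), dtype=bool))


class TestExtractTraits:
    def test_schema_lengths(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:28, 10:20] = True
        rgb = colored(mask)
        assert len(extract_traits(rgb, mask, TraitSchema.full()).values) == 18
        assert len(extract_traits(rgb, mask,
                                  TraitSchema.no_yellow()).values) == 16

    def test_deterministic(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:28, 10:20] = True
        rgb = colored(mask)
        a = extract_traits(rgb, mask).as_array()
        b = extract_traits(rgb, mask).as_array()
        assert np.array_equal(a, b)

    def test_exact_area_identities(self, small_plants):
        """CBA = H*W and TBR*CBA = TPA hold exactly; THR >= TBR."""
        for _, rgb, mask in small_plants[:10]:
            tv = extract_traits(rgb, mask)
            assert tv.CBA == tv.H * tv.W
            assert tv.TBR * tv.CBA == pytest.approx(tv.TPA, abs=1e-9)
            assert tv.THR >= tv.TBR
            assert tv.TPA >= tv.GPA >= 0
            assert tv.TPA >= tv.YPA >= 0
            assert 0.8 <= tv.FDIC <= 2.2

    def test_translation_invariance(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:20, 8:18] = True
        mask[10, 18:30] = True
        rgb = colored(mask)
        base = extract_traits(rgb, mask).as_array()
        shifted_mask = np.roll(np.roll(mask, 7, axis=0), -4, axis=1)
        shifted_rgb = np.roll(np.roll(rgb, 7, axis=0), -4, axis=1)
        moved = extract_traits(shifted_rgb, shifted_mask).as_array()
        assert np.allclose(base, moved, atol=1e-12)

    def test_nearest_upscale_scales_areas(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:15, 5:12] = True
        mask[8, 12:18] = True
        rgb = colored(mask)
        tv = extract_traits(rgb, mask)
        big_mask = mask.repeat(2, axis=0).repeat(2, axis=1)
        big_rgb = rgb.repeat(2, axis=0).repeat(2, axis=1)
        tv2 = extract_traits(big_rgb, big_mask)
        assert tv2.TPA == 4 * tv.TPA
        assert tv2.TBR == pytest.approx(tv.TBR, abs=1e-9)
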