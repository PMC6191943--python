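import itertools

import numpy as np
import pytest
from scipy import ndimage

from histoquant.io import BinaryMask
from histoquant.quant import (
    DistanceHistogram,
    MarkerSegmentation,
    clean_marker_mask,
    histogram_intersection,
    marker_density,
    mean_histogram,
    min_distance_histogram,
)
from histoquant.tissue import TissueRegion


def all_small_components(grid=4, max_size=4):
    """Every 8-connected pixel set of size <= max_size on a small grid."""
    cells = list(itertools.product(range(grid), repeat=2))
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(cells, size):
            m = np.zeros((grid, grid), bool)
            for r, c in combo:
                m[r, c] = True
            _, n = ndimage.label(m, structure=np.ones((3, 3)))
            if n == 1:
                yield combo, m


class TestCleanMarkerMask:
    def test_every_small_component_filtered_by_size(self):
        for combo, m in all_small_components():
            seg = clean_marker_mask(BinaryMask(m))
            if len(combo) < 3:
                assert seg.A_M == 0, f"component {combo} should be removed"
            else:
                assert seg.A_M == len(combo), f"component {combo} should be kept"

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(0)
        m = rng.random((40, 40)) < 0.3
        once = clean_marker_mask(BinaryMask(m))
        assert not (once.M.pixels & ~m).any()
        twice = clean_marker_mask(once.M)
        assert np.array_equal(once.M.pixels, twice.M.pixels)

    def test_two_isolated_pixels_removed(self):
        m = np.zeros((10, 10), bool)
        m[1, 1] = m[8, 8] = True
        assert clean_marker_mask(BinaryMask(m)).A_M == 0

    def test_l_shaped_triple_kept(self):
        m = np.zeros((5, 5), bool)
        m[1, 1] = m[2, 1] = m[2, 2] = True
        assert clean_marker_mask(BinaryMask(m)).A_M == 3

    def test_empty_input_empty_output(self):
        assert clean_marker_mask(BinaryMask(np.zeros((5, 5), bool))).A_M == 0


class TestMarkerDensity:
    def _region(self, h=40, w=25):
        m = np.ones((h, w), bool)
        return TissueRegion.from_mask(BinaryMask(m))

    def test_ten_pixels_in_thousand_is_one_percent(self):
        region = self._region()
        mk = np.zeros((40, 25), bool)
        mk[0, :10] = True
        d = marker_density(MarkerSegmentation.from_mask(BinaryMask(mk)), region)
        assert d.percent == pytest.approx(1.0)

    def test_empty_markers_zero_density(self):
        d = marker_density(
            MarkerSegmentation.from_mask(BinaryMask(np.zeros((40, 25), bool))), self._region()
        )
        assert d.DM == 0.0

    def test_roi_restriction_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mk = rng.random((40, 40)) < 0.1
        roi = np.zeros((40, 40), bool)
        roi[:20, :20] = True
        d = marker_density(MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(roi))
        brute = sum(
            1 for r in range(40) for c in range(40) if mk[r, c] and roi[r, c]
        ) / roi.sum()
        assert d.DM == pytest.approx(brute, abs=1e-12)

    def test_zero_area_region_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            marker_density(
                MarkerSegmentation.from_mask(BinaryMask(np.zeros((5, 5), bool))),
                BinaryMask(np.zeros((5, 5), bool)),
            )


def brute_min_distances(markers: np.ndarray, border: np.ndarray) -> np.ndarray:
    bp = np.argwhere(border)
    out = []
    for r, c in np.argwhere(markers):
        out.append(np.sqrt(((bp - [r, c]) ** 2).sum(axis=1)).min())
    return np.array(out)


class TestMinDistanceHistogram:
    def test_markers_on_border_all_mass_in_bin_zero(self):
        border = np.zeros((10, 10), bool)
        border[5, :] = True
        h = min_distance_histogram(
            MarkerSegmentation.from_mask(BinaryMask(border.copy())), BinaryMask(border)
        )
        assert h.frequencies[0] == 1.0

    def test_known_distances_one_one_three_three(self):
        border = np.zeros((10, 10), bool)
        border[0, :] = True
        mk = np.zeros((10, 10), bool)
        mk[1, 2] = mk[1, 7] = mk[3, 2] = mk[3, 7] = True
        h = min_distance_histogram(MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(border))
        assert np.allclose(h.frequencies, [0, 0.5, 0, 0.5])

    def test_band_limit_filters_then_renormalizes(self):
        border = np.zeros((10, 10), bool)
        border[0, :] = True
        mk = np.zeros((10, 10), bool)
        mk[1, 2] = mk[1, 7] = mk[3, 2] = mk[3, 7] = True
        h = min_distance_histogram(
            MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(border), band_limit_px=2
        )
        assert h.frequencies.sum() == pytest.approx(1.0)
        assert h.frequencies[1] == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            border = rng.random((48, 48)) < 0.02
            mk = rng.random((48, 48)) < 0.05
            if not border.any() or not mk.any():
                continue
            h = min_distance_histogram(
                MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(border)
            )
            d = brute_min_distances(mk, border)
            expected = np.bincount(np.floor(d).astype(int)) / d.size
            assert np.allclose(h.frequencies, expected)
            assert h.frequencies.sum() == pytest.approx(1.0)

    def test_no_marker_in_band_is_an_error(self):
        border = np.zeros((10, 10), bool)
        border[0, 0] = True
        mk = np.zeros((10, 10), bool)
        mk[9, 9] = True
        with pytest.raises(ValueError, match="band"):
            min_distance_histogram(
                MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(border), band_limit_px=2
            )

    def test_empty_border_rejected(self):
        mk = np.zeros((5, 5), bool)
        mk[1, 1] = True
        with pytest.raises(ValueError, match="border"):
            min_distance_histogram(
                MarkerSegmentation.from_mask(BinaryMask(mk)), BinaryMask(np.zeros((5, 5), bool))
            )


def hist(freqs, width=1.0, band=np.inf):
    return DistanceHistogram(bin_width_px=width, band_limit_px=band, frequencies=np.array(freqs))


class TestMeanHistogram:
    def test_identical_inputs_unchanged(self):
        h = hist([0.25, 0.75])
        m = mean_histogram([h, h, h])
        assert np.allclose(m.frequencies, [0.25, 0.75])

    def test_two_one_hots_average_to_half_half(self):
        m = mean_histogram([hist([1.0, 0.0]), hist([0.0, 1.0])])
        assert np.allclose(m.frequencies, [0.5, 0.5])

    def test_random_histograms_match_manual_average(self):
        rng = np.random.default_rng(3)
        hs = []
        for _ in range(3):
            f = rng.random(6)
            hs.append(hist(f / f.sum()))
        m = mean_histogram(hs)
        manual = np.mean([h.frequencies for h in hs], axis=0)
        assert np.allclose(m.frequencies, manual / manual.sum())
        assert m.frequencies.sum() == pytest.approx(1.0)

    def test_unequal_lengths_padded_with_zeros(self):
        m = mean_histogram([hist([1.0]), hist([0.0, 1.0])])
        assert np.allclose(m.frequencies, [0.5, 0.5])

    def test_mixed_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            mean_histogram([hist([1.0]), hist([1.0], width=2.0)])


class TestHistogramIntersection:
    def test_identical_histograms_intersect_fully(self):
        h = hist([0.2, 0.8])
        assert histogram_intersection(h, h) == pytest.approx(1.0)

    def test_disjoint_supports_intersect_zero(self):
        assert histogram_intersection(hist([1.0, 0.0]), hist([0.0, 1.0])) == 0.0

    def test_hand_computed_example(self):
        assert histogram_intersection(hist([0.7, 0.3]), hist([0.4, 0.6])) == pytest.approx(0.7)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b = rng.random(5), rng.random(5)
            ha, hb = hist(a / a.sum()), hist(b / b.sum())
            v = histogram_intersection(ha, hb)
            assert v == pytest.approx(histogram_intersection(hb, ha))
            assert 0.0 <= v <= 1.0 + 1e-12

    def test_unity_only_for_equal_histograms(self):
        a = hist([0.5, 0.5])
        b = hist([0.4999, 0.5001])
        assert histogram_intersection(a, b) < 1.0

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            histogram_intersection(hist([0.0, 0.0]), hist([1.0, 0.0]))
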