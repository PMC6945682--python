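import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lapdepth as ld
from lapdepth.stereo_core import (CostVolume, SENTINEL, census_transform,
                                  winning_cost)


def census_oracle(image, ww, wh):
    """Brute-force census transform: explicit neighbour comparison loop."""
    h, w = image.shape
    rw, rh = ww // 2, wh // 2
    padded = np.pad(image, ((rh, rh), (rw, rw)), mode="edge")
    out = np.zeros((h, w), dtype=np.uint64)
    for y in range(h):
        for x in range(w):
            bits = []
            for dy in range(-rh, rh + 1):
                for dx in range(-rw, rw + 1):
                    if dy == 0 and dx == 0:
                        continue
                    bits.append(int(padded[y + rh + dy, x + rw + dx]
                                    < image[y, x]))
            out[y, x] = int("".join(map(str, bits)), 2)
    return out


class TestCensusTransform:
    def test_constant_image_gives_all_zero_strings(self):
        cen = census_transform(np.full((8, 8), 0.5), 3, 3)
        assert (cen == 0).all()

    def test_hand_computed_centre_bits(self):
        img = np.arange(1, 10).reshape(3, 3) / 10.0
        cen = census_transform(img, 3, 3)
        # neighbours 1,2,3,4 < 5 -> bits 11110000
        assert cen[1, 1] == int("11110000", 2)

    def test_invariant_to_additive_shift_and_gamma(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        base = census_transform(img, 5, 3)
        np.testing.assert_array_equal(base, census_transform(img + 0.3, 5, 3))
        np.testing.assert_array_equal(base, census_transform(img ** 2, 5, 3))

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        img = rng.random((10, 12))
        np.testing.assert_array_equal(census_transform(img, 5, 3),
                                      census_oracle(img, 5, 3))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            census_transform(np.zeros((8, 8)), 4, 3)


class TestCostVolumes:
    def test_identical_images_zero_cost_at_zero_disparity(self):
        rng = np.random.default_rng(2)
        img = rng.random((8, 8))
        cen = census_transform(img, 3, 3)
        vol = ld.hamming_cost(cen, cen, (0, 3))
        assert (vol.costs[0] == 0).all()
        ad = ld.ad_cost(img, img, (0, 3))
        assert (ad.costs[0] == 0).all()

    def test_hamming_matches_bit_count_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        ca, cb = census_transform(a, 5, 5), census_transform(b, 5, 5)
        vol = ld.hamming_cost(ca, cb, (0, 6))
        for d in range(0, 7):
            for y in range(16):
                for x in range(16):
                    if x - d < 0:
                        assert vol.costs[d, y, x] == SENTINEL
                    else:
                        expect = bin(int(ca[y, x]) ^ int(cb[y, x - d])).count("1")
                        assert vol.costs[d, y, x] == expect

    def test_ad_matches_per_pixel_loop(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        vol = ld.ad_cost(a, b, (1, 4))
        for i, d in enumerate(range(1, 5)):
            for y in range(8):
                for x in range(8):
                    if x - d < 0:
                        assert vol.costs[i, y, x] == SENTINEL
                    else:
                        np.testing.assert_allclose(
                            vol.costs[i, y, x], abs(a[y, x] - b[y, x - d]))

    def test_ad_cost_of_matched_intensities(self):
        a = np.full((8, 8), 0.75)
        b = np.full((8, 8), 0.25)
        vol = ld.ad_cost(a, b, (0, 0))
        np.testing.assert_allclose(vol.costs[0], 0.5)


class TestCombine:
    def test_zero_costs_combine_to_zero(self):
        z = CostVolume(np.zeros((2, 4, 4)), 0, 1)
        out = ld.combine_ad_census(z, z, 10.0, 30.0)
        np.testing.assert_array_equal(out.costs, 0.0)

    def test_saturates_at_two(self):
        big = CostVolume(np.full((2, 4, 4), 1e9), 0, 1)
        out = ld.combine_ad_census(big, big, 10.0, 30.0)
        np.testing.assert_allclose(out.costs, 2.0)

    def test_closed_form_at_lambda(self):
        ad = CostVolume(np.full((2, 4, 4), 10.0), 0, 1)
        cen = CostVolume(np.full((2, 4, 4), 30.0), 0, 1)
        out = ld.combine_ad_census(ad, cen, 10.0, 30.0)
        np.testing.assert_allclose(out.costs, 2 * (1 - np.exp(-1)))

    def test_nonpositive_lambda_rejected(self):
        z = CostVolume(np.zeros((2, 4, 4)), 0, 1)
        with pytest.raises(ValueError):
            ld.combine_ad_census(z, z, 0.0, 30.0)

    def test_sentinels_propagate(self):
        c = np.zeros((2, 4, 4))
        c[0, 0, 0] = SENTINEL
        out = ld.combine_ad_census(CostVolume(c, 0, 1),
                                   CostVolume(np.zeros((2, 4, 4)), 0, 1),
                                   10.0, 30.0)
        assert out.costs[0, 0, 0] == SENTINEL

    @given(st.floats(0, 100), st.floats(0, 60))
    @settings(deadline=None, max_examples=50)
    def test_combined_cost_always_in_unit_interval_pair(self, c_ad, c_cen):
        ad = CostVolume(np.full((2, 2, 2), c_ad), 0, 1)
        cen = CostVolume(np.full((2, 2, 2), c_cen), 0, 1)
        out = ld.combine_ad_census(ad, cen, 10.0, 30.0)
        assert (out.costs >= 0).all() and (out.costs <= 2).all()


class TestAggregate:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(5)
        vol = CostVolume(rng.random((3, 8, 8)), 0, 2)
        out = ld.aggregate_costs(vol, 1)
        np.testing.assert_array_equal(out.costs, vol.costs)

    def test_constant_slice_unchanged(self):
        vol = CostVolume(np.full((3, 8, 8), 0.7), 0, 2)
        out = ld.aggregate_costs(vol, 3)
        np.testing.assert_allclose(out.costs, 0.7)

    def test_matches_neighbourhood_mean_oracle(self):
        rng = np.random.default_rng(6)
        vol = CostVolume(rng.random((2, 8, 8)), 0, 1)
        out = ld.aggregate_costs(vol, 3)
        padded = np.pad(vol.costs, ((0, 0), (1, 1), (1, 1)), mode="edge")
        for d in range(2):
            for y in range(8):
                for x in range(8):
                    window = padded[d, y:y + 3, x:x + 3]
                    np.testing.assert_allclose(out.costs[d, y, x],
                                               window.mean(), rtol=1e-12)

    def test_sentinels_excluded_from_neighbour_means(self):
        c = np.zeros((1, 4, 4))
        c[0, 0, 0] = SENTINEL
        out = ld.aggregate_costs(CostVolume(c, 0, 0), 3)
        assert out.costs[0, 0, 0] == SENTINEL  # sentinel cell stays sentinel
        assert np.isfinite(out.costs[0, 0, 1])  # neighbour ignores it


class TestWTA:
    def test_integer_argmin(self):
        c = np.array([5.0, 1.0, 3.0]).reshape(3, 1, 1)
        d = ld.wta_disparity(CostVolume(c, 0, 2), subpixel=False)
        assert d.values[0, 0] == 1

    def test_symmetric_curve_refines_to_centre(self):
        c = np.array([3.0, 1.0, 3.0]).reshape(3, 1, 1)
        d = ld.wta_disparity(CostVolume(c, 0, 2), subpixel=True)
        assert d.values[0, 0] == 1.0

    def test_parabolic_offset_closed_form(self):
        c = np.array([4.0, 1.0, 2.0]).reshape(3, 1, 1)
        d = ld.wta_disparity(CostVolume(c, 0, 2), subpixel=True)
        np.testing.assert_allclose(d.values[0, 0], 1.25)

    def test_ties_break_toward_smaller_disparity(self):
        c = np.array([2.0, 1.0, 1.0, 2.0]).reshape(4, 1, 1)
        d = ld.wta_disparity(CostVolume(c, 0, 3), subpixel=False)
        assert d.values[0, 0] == 1

    def test_all_sentinel_pixel_marked_invalid(self):
        c = np.full((3, 2, 2), SENTINEL)
        c[:, 0, 0] = [3.0, 1.0, 2.0]
        d = ld.wta_disparity(CostVolume(c, 1, 3), subpixel=True)
        assert d.values[1, 1] == 0.0
        assert d.values[0, 0] != 0.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_wta_agrees_with_argmin_loop(self, seed):
        rng = np.random.default_rng(seed)
        costs = rng.random((5, 4, 4))
        vol = CostVolume(costs, 0, 4)
        d = ld.wta_disparity(vol, subpixel=False)
        np.testing.assert_array_equal(d.values, costs.argmin(axis=0))


class TestMatchStereo:
    def test_constant_scene_recovered(self, constant_scene):
        d_l, d_r, _, _ = ld.match_stereo(constant_scene.pair,
                                         ld.StereoParams(1, 10))
        ok = constant_scene.validity > 0
        frac = (np.abs(d_l.values - 5.0) <= 1.0)[ok].mean()
        assert frac >= 0.99

    def test_zero_disparity_identical_pair(self):
        tex = ld.make_texture(48, 48, 4, seed=8)
        pair = ld.StereoPair(left=tex, right=tex.copy())
        d_l, _, _, _ = ld.match_stereo(pair, ld.StereoParams(0, 6))
        assert np.abs(d_l.values).max() <= 0.5

    def test_smooth_scene_median_error_below_one_pixel(self, matched_scene):
        scene, d_l, _, _, _ = matched_scene
        ok = scene.validity > 0
        err = np.abs(d_l.values - scene.gt_disparity)[ok]
        assert np.median(err) <= 1.0

    def test_flip_swap_symmetry_reproduces_right_view(self, constant_scene):
        params = ld.StereoParams(1, 10)
        _, d_r, _, _ = ld.match_stereo(constant_scene.pair, params)
        mirrored = ld.StereoPair(
            left=constant_scene.pair.right[:, ::-1],
            right=constant_scene.pair.left[:, ::-1])
        d_l_m, _, _, _ = ld.match_stereo(mirrored, params)
        np.testing.assert_allclose(d_l_m.values[:, ::-1], d_r.values,
                                   atol=1e-12)

    def test_cost_volume_range_contract(self, matched_scene):
        _, _, _, vol_l, vol_r = matched_scene
        for vol in (vol_l, vol_r):
            finite = np.isfinite(vol.costs)
            assert (vol.costs[finite] >= 0).all()
            assert (vol.costs[finite] <= 2).all()


def test_winning_cost_is_minimum_over_finite_cells():
    c = np.array([[[3.0]], [[SENTINEL]], [[2.0]]])
    assert winning_cost(CostVolume(c, 0, 2))[0, 0] == 2.0
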