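import numpy as np
import pytest

import lapdepth as ld
from lapdepth import autodiff as ad
from lapdepth.confidence import ProxyLabel
from lapdepth.losses import (LossWeights, bilinear_warp, downsample_proxy,
                             lr_consistency_loss,
                             neighbourhood_smoothness_loss, photometric_loss,
                             proxy_label_loss, ssim_map, total_loss)


def numeric_gradient(fn, x0, eps=1e-6):
    """Central-difference gradient of a scalar loss w.r.t. an array."""
    num = np.zeros_like(x0)
    for idx in np.ndindex(*x0.shape):
        xp, xm = x0.copy(), x0.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num[idx] = (float(fn(ad.Tensor(xp))) - float(fn(ad.Tensor(xm)))) / (2 * eps)
    return num


def analytic_gradient(fn, x0):
    x = ad.Tensor(x0, requires_grad=True)
    fn(x).backward()
    return x.grad


class TestBilinearWarp:
    def test_zero_disparity_is_identity(self):
        rng = np.random.default_rng(0)
        src = rng.random((8, 8))
        out, mask = bilinear_warp(src, np.zeros((8, 8)), "left")
        np.testing.assert_allclose(out.data, src)
        assert mask.all()

    @pytest.mark.parametrize("d", [3, 7])
    def test_constant_disparity_masks_exactly_d_columns(self, d):
        h, w = 10, 16
        src = np.random.default_rng(1).random((h, w))
        _, mask = bilinear_warp(src, np.full((h, w), float(d)), "left")
        assert (mask == 0).sum() == d * h
        assert (mask[:, :d] == 0).all()

    def test_reconstructs_left_view_from_right(self, smooth_scene):
        rec, mask = bilinear_warp(smooth_scene.pair.right,
                                  smooth_scene.gt_disparity, "left")
        ok = (mask > 0) & (smooth_scene.validity > 0)
        assert np.abs(rec.data - smooth_scene.pair.left)[ok].mean() < 0.02

    def test_direction_validated(self):
        with pytest.raises(ValueError):
            bilinear_warp(np.zeros((4, 4)), np.zeros((4, 4)), "up")


class TestSSIM:
    def test_self_similarity_is_one(self):
        img = np.random.default_rng(2).random((8, 8))
        np.testing.assert_allclose(ssim_map(img, img).data, 1.0)

    def test_constant_zero_vs_one_degenerates(self):
        s = ssim_map(np.zeros((8, 8)), np.ones((8, 8))).data
        assert np.all(s < 0.01)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        np.testing.assert_allclose(ssim_map(a, b).data, ssim_map(b, a).data)

    def test_bounded(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        s = ssim_map(a, b).data
        assert (s >= -1).all() and (s <= 1).all()


class TestPhotometricLoss:
    def test_exact_reconstruction_is_zero(self):
        img = np.random.default_rng(5).random((8, 8))
        assert float(photometric_loss(img, img, np.ones((8, 8)))) == 0.0

    def test_pure_l1_constant_residual(self):
        img = np.zeros((8, 8))
        loss = photometric_loss(img, img + 0.1, np.ones((8, 8)),
                                alpha_ssim=0.0)
        np.testing.assert_allclose(float(loss), 0.1, rtol=1e-6)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(6)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        loss = float(photometric_loss(a, b, np.ones((8, 8)), alpha_ssim=0.85))
        ssim = ssim_map(ad.Tensor(a), ad.Tensor(b)).data
        expected = (0.85 * (1 - ssim) / 2 + 0.15 * np.abs(a - b)).mean()
        np.testing.assert_allclose(loss, expected, rtol=1e-6)

    def test_empty_mask_warns_and_returns_zero(self):
        img = np.random.default_rng(7).random((6, 6))
        with pytest.warns(UserWarning):
            loss = photometric_loss(img, img + 1, np.zeros((6, 6)))
        assert float(loss) == 0.0


class TestLRConsistency:
    def test_constant_fields_self_consistent(self):
        d = np.full((6, 8), 2.0)
        assert float(lr_consistency_loss(d, d)) < 1e-12

    def test_geometrically_consistent_pair(self, smooth_scene):
        gt = smooth_scene.gt_disparity
        h, w = gt.shape
        cols = np.arange(w)
        d_r = np.zeros_like(gt)
        for y in range(h):
            t = np.round(cols - gt[y]).astype(int)
            ok = t >= 0
            d_r[y, t[ok]] = gt[y, ok]
        # fill holes in the constructed right map by nearest valid value
        for y in range(h):
            row = d_r[y]
            valid = np.nonzero(row)[0]
            row[:] = np.interp(cols, valid, row[valid])
        assert float(lr_consistency_loss(gt, d_r)) < 0.2

    def test_hand_built_maps(self):
        d_l = np.array([[0.0, 1.0, 1.0, 2.0]])
        d_r = np.array([[1.0, 1.0, 2.0, 0.0]])
        # left term, samples d_r at x - d_l: |0-1|, |1-1|, |1-1|, |2-1|
        #   -> mean 0.5
        # right term, samples d_l at x + d_r: x=0 -> |1-d_l(1)|=0,
        #   x=1 -> |1-d_l(2)|=0, x=2 -> column 4 is out of image (masked),
        #   x=3 -> |0-d_l(3)|=2 -> mean over the 3 valid pixels = 2/3
        expected = 0.5 + 2.0 / 3.0
        np.testing.assert_allclose(float(lr_consistency_loss(d_l, d_r)),
                                   expected)


class TestProxyLabelLoss:
    def test_exact_agreement_is_zero(self):
        d = np.full((6, 8), 4.0)
        proxy = ProxyLabel(np.where(np.arange(8) >= 4, 4.0, 0.0)
                           * np.ones((6, 1)))
        assert float(proxy_label_loss(d, d, proxy)) == 0.0

    def test_single_pixel_hand_example(self):
        # support = one pixel with d~=2, d_l=3; d_r at the matched column = 2
        d_l = np.zeros((1, 6))
        d_l[0, 4] = 3.0
        d_r = np.full((1, 6), 2.0)
        proxy = np.zeros((1, 6))
        proxy[0, 4] = 2.0
        loss = proxy_label_loss(d_l, d_r, ProxyLabel(proxy))
        np.testing.assert_allclose(float(loss), 1.0)

    def test_mean_normalisation_invariant_to_support_size(self):
        d_l = np.full((4, 8), 3.0)
        d_r = np.full((4, 8), 2.0)
        small = np.zeros((4, 8))
        small[0, 6] = 2.0
        big = np.zeros((4, 8))
        big[:, 6] = 2.0
        l_small = float(proxy_label_loss(d_l, d_r, ProxyLabel(small)))
        l_big = float(proxy_label_loss(d_l, d_r, ProxyLabel(big)))
        np.testing.assert_allclose(l_small, l_big)

    def test_empty_support_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            loss = proxy_label_loss(np.ones((4, 4)), np.ones((4, 4)),
                                    ProxyLabel(np.zeros((4, 4))))
        assert float(loss) == 0.0

    def test_out_of_image_samples_drop_second_term(self):
        # support pixel at x=1 with d=3 samples column -2: only |d_l - d~|
        d_l = np.full((1, 6), 3.0)
        d_r = np.full((1, 6), 99.0)
        proxy = np.zeros((1, 6))
        proxy[0, 1] = 2.0
        np.testing.assert_allclose(
            float(proxy_label_loss(d_l, d_r, ProxyLabel(proxy))), 1.0)


class TestSmoothness:
    def test_constant_disparity_is_zero(self):
        f = np.random.default_rng(8).random((6, 6))
        assert float(neighbourhood_smoothness_loss(np.full((6, 6), 3.0),
                                                   f, 1.0, 10.0)) == 0.0

    def test_two_pixel_closed_forms(self):
        D = np.array([[0.0, 1.0]])
        same = neighbourhood_smoothness_loss(D, np.array([[0.0, 0.0]]), 1.0, 1.0)
        np.testing.assert_allclose(float(same), 1.0)
        diff = neighbourhood_smoothness_loss(D, np.array([[0.0, 1.0]]), 1.0, 1.0)
        np.testing.assert_allclose(float(diff), np.exp(-1))

    def test_negative_constants_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            neighbourhood_smoothness_loss(D, D, -1.0, 1.0)
        with pytest.raises(ValueError):
            neighbourhood_smoothness_loss(D, D, 1.0, -1.0)


class TestTotalLoss:
    def test_zero_terms(self):
        terms = [{"r": 0.0, "rc": 0.0, "p": 0.0, "s": 0.0}] * 4
        assert float(total_loss(terms)) == 0.0

    def test_published_weights_on_unit_terms(self):
        terms = [{"r": 1.0, "rc": 1.0, "p": 1.0, "s": 1.0}]
        np.testing.assert_allclose(float(total_loss(terms)), 2.6)

    def test_linearity(self):
        rng = np.random.default_rng(9)
        terms = [{k: rng.random() for k in ("r", "rc", "p", "s")}
                 for _ in range(4)]
        doubled = [{k: 2 * v for k, v in t.items()} for t in terms]
        np.testing.assert_allclose(float(total_loss(doubled)),
                                   2 * float(total_loss(terms)), rtol=1e-12)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)
        with pytest.raises(ValueError):
            LossWeights(alpha_ssim=1.5)


class TestExactSolutionFixture:
    """With network outputs equal to the true disparity of a noiseless
    constant-disparity scene (warps then have no interpolation error),
    every loss term vanishes."""

    def test_all_losses_zero(self, constant_scene):
        gt = constant_scene.gt_disparity
        left, right = constant_scene.pair.left, constant_scene.pair.right
        rec_l, mask_l = bilinear_warp(right, gt, "left")
        assert float(photometric_loss(left, rec_l.data, mask_l)) < 1e-10
        assert float(lr_consistency_loss(gt, gt)) < 1e-10
        proxy = ProxyLabel(np.where(constant_scene.validity > 0, gt, 0.0))
        assert float(proxy_label_loss(gt, gt, proxy)) < 1e-10
        feats = left
        assert float(neighbourhood_smoothness_loss(gt, feats)) == 0.0


@pytest.fixture(scope="module")
def inputs():
    rng = np.random.default_rng(10)
    return {
        "I": rng.random((6, 6)), "I_r": rng.random((6, 6)),
        "d0": rng.random((6, 6)) * 2 + 1,
        "proxy": np.where(rng.random((6, 6)) > 0.5,
                          rng.random((6, 6)) * 2 + 1, 0.0),
        "feat": rng.random((6, 6)),
    }


class TestGradients:
    """Analytic gradients of every loss w.r.t. disparity match central
    differences on random 6x6 inputs."""

    def check(self, fn, x0, tol=1e-4):
        num = numeric_gradient(fn, x0)
        ana = analytic_gradient(fn, x0)
        denom = max(np.abs(num).max(), 1e-8)
        assert np.abs(ana - num).max() / denom < tol

    def test_photometric(self, inputs):
        I, I_r = inputs["I"], inputs["I_r"]
        _, mask = ad.warp1d(I_r, inputs["d0"], -1)

        def fn(d):
            rec, _ = ad.warp1d(ad.as_tensor(I_r), d, -1)
            return photometric_loss(I, rec, mask)

        self.check(fn, inputs["d0"])

    def test_lr_consistency(self, inputs):
        d_r = inputs["I_r"] * 3
        self.check(lambda d: lr_consistency_loss(d, d_r), inputs["d0"])

    def test_proxy_label(self, inputs):
        proxy = ProxyLabel(inputs["proxy"])
        d_r = inputs["I_r"] * 3
        self.check(lambda d: proxy_label_loss(d, d_r, proxy), inputs["d0"])

    def test_smoothness(self, inputs):
        self.check(lambda d: neighbourhood_smoothness_loss(
            d, inputs["feat"], 1.0, 10.0), inputs["d0"])

    def test_smoothness_gradient_wrt_features(self, inputs):
        self.check(lambda f: neighbourhood_smoothness_loss(
            ad.as_tensor(inputs["d0"]), f, 1.0, 10.0), inputs["feat"])


class TestProxyDownsampling:
    def test_values_divided_by_factor_support_decimated(self):
        d = np.zeros((8, 8))
        d[::2, ::2] = 6.0
        down = downsample_proxy(ProxyLabel(d), 2)
        assert down.d_tilde.shape == (4, 4)
        np.testing.assert_array_equal(down.d_tilde, 3.0)
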