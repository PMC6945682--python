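"""Training losses for the self-supervised disparity network.

Four terms drive training, each evaluated at four scales and summed with
weights (alpha, beta, gamma, phi) = (1.0, 1.0, 0.1, 0.5):

* photometric reconstruction L_r — SSIM + L1 between each image and its
  reconstruction warped from the other view;
* left-right disparity consistency L_rc — each view's disparity must agree
  with the other view's disparity sampled at the matching column;
* proxy-label L_p — L1 pull of both predicted maps toward the sparse
  classical-stereo proxy label over its support, normalised by the support
  size N_p;
* neighbourhood smoothness L_s — squared disparity jumps between
  4-neighbours, down-weighted by exp(-t (f_i - f_j)^2) where f is a decoder
  feature plane, so appearance edges may keep depth edges.

Every term averages over "principled" masks: pixels whose matching
coordinate falls outside the other view are excluded analytically. The
package-wide sign convention is disparity >= 0 with right column = left
column - d, so reconstructing the left view samples the right image at
x - d_l (sign -1) and reconstructing the right samples the left at x + d_r.

Functions accept numpy arrays or autodiff Tensors and return Tensors
(float() gives the scalar); gradients flow to every Tensor input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .confidence import ProxyLabel

#: Sign of the warp that reconstructs each view (left: sample right at x-d).
WARP_SIGN = {"left": -1, "right": +1}


@dataclass
class LossWeights:
    """Loss-term weights; the defaults are the published operating point."""

    alpha: float = 1.0       # photometric L_r
    beta: float = 1.0        # left-right consistency L_rc
    gamma: float = 0.1       # proxy label L_p
    phi: float = 0.5         # neighbourhood smoothness L_s
    lambda_s: float = 1.0    # scale inside L_s (kept 1; phi already weights)
    t: float = 10.0          # feature-contrast rate inside L_s
    alpha_ssim: float = 0.85

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "phi", "lambda_s", "t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.alpha_ssim <= 1.0:
            raise ValueError("alpha_ssim must lie in [0, 1]")


def bilinear_warp(source, disparity, direction: str = "left"):
    """Reconstruct a view by sampling ``source`` along rows.

    ``direction`` names the output view: 'left' samples the (right-view)
    source at x - d, 'right' samples the (left-view) source at x + d.
    Returns (reconstruction, principled mask); the mask is 1 exactly where
    the analytic sampling coordinate x -/+ d lies inside [0, W-1].
    """
    if direction not in WARP_SIGN:
        raise ValueError("direction must be 'left' or 'right'")
    out, mask = ad.warp1d(source, disparity, WARP_SIGN[direction])
    return out, mask


def _erode_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Shrink a validity mask so no kept pixel's window touches an invalid
    one (image borders replicate and stay valid)."""
    if radius == 0:
        return mask
    size = (1,) * (mask.ndim - 2) + (2 * radius + 1,) * 2
    return minimum_filter(mask, size=size, mode="nearest")


def ssim_map(a, b, window: int = 3) -> Tensor:
    """Per-pixel SSIM with mean pooling, C1 = 0.01^2, C2 = 0.03^2."""
    a, b = as_tensor(a), as_tensor(b)
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    r = window // 2

    def pool(t):
        return ad.box_filter(ad.pad_edge2d(t, r), window)

    mu_a, mu_b = pool(a), pool(b)
    var_a = pool(a * a) - mu_a * mu_a
    var_b = pool(b * b) - mu_b * mu_b
    cov = pool(a * b) - mu_a * mu_b
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return num / den


def photometric_loss(image, reconstruction, mask, alpha_ssim: float = 0.85,
                     ssim_window: int = 3) -> Tensor:
    """Masked mean of alpha*(1 - SSIM)/2 + (1 - alpha)*L1 for one view.

    The mask is eroded by the SSIM window radius so that only pixels whose
    whole comparison window is valid contribute; an exact reconstruction
    then scores exactly zero.
    """
    image, reconstruction = as_tensor(image), as_tensor(reconstruction)
    mask = np.broadcast_to(np.asarray(mask, dtype=image.data.dtype),
                           image.data.shape)
    mask = _erode_mask(mask, ssim_window // 2)
    l1 = ad.absolute(image - reconstruction)
    per_pixel = (1.0 - alpha_ssim) * l1
    if alpha_ssim > 0:
        dssim = (1.0 - ssim_map(image, reconstruction, ssim_window)) * 0.5
        per_pixel = per_pixel + alpha_ssim * dssim
    return ad.masked_mean(per_pixel, mask)


def lr_consistency_loss(d_l, d_r, masks=None) -> Tensor:
    """Mutual agreement of the two disparity maps at matched columns.

    For the left view: mean over valid pixels of |d_l(x) - d_r(x - d_l(x))|
    (bilinear sample), plus the mirrored right-view term.
    """
    d_l, d_r = as_tensor(d_l), as_tensor(d_r)
    total = Tensor(np.zeros((), dtype=d_l.data.dtype))
    for view, ref, other in (("left", d_l, d_r), ("right", d_r, d_l)):
        sampled, warp_mask = ad.warp1d(other, ref, WARP_SIGN[view])
        mask = warp_mask
        if masks is not None:
            mask = mask * np.asarray(masks[view], dtype=mask.dtype)
        total = total + ad.masked_mean(ad.absolute(ref - sampled), mask)
    return total


def proxy_label_loss(d_l, d_r, proxy: ProxyLabel) -> Tensor:
    """L1 pull of both branches toward the sparse proxy label.

    L_p = (1/N_p) sum over the support of |d_l - d~| plus |d_r sampled at
    the matching column - d~|; samples that leave the image contribute only
    the first term. An empty support defines L_p = 0 (with a warning).
    """
    d_l, d_r = as_tensor(d_l), as_tensor(d_r)
    d_tilde = np.asarray(proxy.d_tilde, dtype=d_l.data.dtype)
    support = (d_tilde != 0).astype(d_l.data.dtype)
    n_p = float(support.sum())
    if n_p == 0:
        warnings.warn("proxy label has empty support; L_p defined as 0",
                      stacklevel=2)
        return Tensor(np.zeros((), dtype=d_l.data.dtype))
    sampled_r, warp_mask = ad.warp1d(d_r, d_l, WARP_SIGN["left"])
    term_l = ad.absolute(d_l - d_tilde) * support
    term_r = ad.absolute(sampled_r - d_tilde) * (support * warp_mask)
    return (term_l.sum() + term_r.sum()) / n_p


def neighbourhood_smoothness_loss(disparity, features, lambda_s: float = 1.0,
                                  t: float = 10.0) -> Tensor:
    """Appearance-gated quadratic smoothness over 4-neighbour pairs.

    lambda * mean over horizontally and vertically adjacent pairs (i, j) of
    (D_i - D_j)^2 exp(-t (f_i - f_j)^2); normalising by the pair count makes
    the weight phi resolution-independent.
    """
    if lambda_s < 0 or t < 0:
        raise ValueError("lambda_s and t must be non-negative")
    d = as_tensor(disparity)
    f = as_tensor(features)
    if f.data.shape != d.data.shape:
        raise ValueError("features must be spatially aligned with disparity")

    def pair_term(a, b, fa, fb):
        return (ad.square(a - b) * ad.exp(-t * ad.square(fa - fb))).sum()

    h_pairs = pair_term(d[..., :, 1:], d[..., :, :-1],
                        f[..., :, 1:], f[..., :, :-1])
    total = h_pairs
    n_pairs = d.data[..., :, 1:].size
    if d.data.shape[-2] > 1:
        v_pairs = pair_term(d[..., 1:, :], d[..., :-1, :],
                            f[..., 1:, :], f[..., :-1, :])
        total = total + v_pairs
        n_pairs += d.data[..., 1:, :].size
    return lambda_s * total / n_pairs


def total_loss(per_scale_terms, weights: LossWeights | None = None) -> Tensor:
    """Weighted sum alpha L_r + beta L_rc + gamma L_p + phi L_s over scales.

    ``per_scale_terms`` is a sequence (one entry per scale, coarse to fine)
    of mappings with keys 'r', 'rc', 'p', 's'.
    """
    if weights is None:
        weights = LossWeights()
    total = None
    for terms in per_scale_terms:
        scale_sum = (weights.alpha * as_tensor(terms["r"])
                     + weights.beta * as_tensor(terms["rc"])
                     + weights.gamma * as_tensor(terms["p"])
                     + weights.phi * as_tensor(terms["s"]))
        total = scale_sum if total is None else total + scale_sum
    return total if total is not None else Tensor(np.zeros(()))


def downsample_proxy(proxy: ProxyLabel, factor: int) -> ProxyLabel:
    """Proxy label at a coarser scale: nearest-neighbour decimation of the
    support with values divided by the scale factor (disparities are
    resolution-dependent; decimation preserves sparsity semantics)."""
    if factor == 1:
        return proxy
    return ProxyLabel(proxy.d_tilde[::factor, ::factor] / factor)


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by a power-of-two factor (trailing 2 axes)."""
    if factor == 1:
        return image
    h, w = image.shape[-2:]
    if h % factor or w % factor:
        raise ValueError("image size must be divisible by the scale factor")
    shaped = image.reshape(*image.shape[:-2], h // factor, factor,
                           w // factor, factor)
    return shaped.mean(axis=(-3, -1))
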