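"""Classical AD-CENSUS stereo matching.

The pipeline computes, per pixel and candidate disparity, a census (Hamming)
cost and an absolute-difference cost, combines them with the robust
saturating transform rho(c, lambda) = 1 - exp(-c / lambda), box-aggregates
each disparity slice, and reads the disparity off by winner-take-all with
optional parabolic sub-pixel refinement. Both a left-referenced and a
right-referenced pass are run so that left-right consistency and the other
confidence measures can be computed downstream.

Cost volumes are indexed [d, y, x] with d = d_min .. d_max; cells whose
matching coordinate falls outside the other view hold ``SENTINEL`` (+inf)
and are never selected as winners unless a pixel has no finite cost at all,
in which case the disparity is marked invalid (0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .io import to_gray

SENTINEL = np.inf

#: Published constants of the AD-CENSUS cost combination; lambda_ad is on
#: the 8-bit intensity scale and is rescaled internally for [0,1] images.
DEFAULT_CENSUS_WINDOW = (9, 7)  # (width, height)
DEFAULT_AGG_WINDOW = 7
DEFAULT_LAMBDA_CENSUS = 30.0
DEFAULT_LAMBDA_AD = 10.0


@dataclass
class CostVolume:
    """Per-pixel, per-disparity matching costs."""

    costs: np.ndarray  # (n_disp, H, W)
    d_min: int
    d_max: int
    view: str = "left"  # 'left' | 'right' reference

    @property
    def disparities(self) -> np.ndarray:
        return np.arange(self.d_min, self.d_max + 1)

    def __post_init__(self) -> None:
        if self.costs.shape[0] != self.d_max - self.d_min + 1:
            raise ValueError("cost volume depth does not match d_range")


@dataclass
class DisparityMap:
    """Per-pixel disparity in pixels; 0 marks an invalid pixel."""

    values: np.ndarray
    view: str = "left"


@dataclass
class StereoParams:
    d_min: int = 1
    d_max: int = 16
    census_window: tuple[int, int] = DEFAULT_CENSUS_WINDOW
    agg_window: int = DEFAULT_AGG_WINDOW
    lambda_ad: float = DEFAULT_LAMBDA_AD
    lambda_census: float = DEFAULT_LAMBDA_CENSUS
    subpixel: bool = True


# -------------------------------------------------------------- census

def census_transform(image: np.ndarray, window_w: int = 9,
                     window_h: int = 7) -> np.ndarray:
    """Census bit strings packed into uint64, one per pixel.

    Bit k (most significant first) is 1 iff the k-th neighbour in row-major
    window order (centre excluded) is strictly darker than the centre.
    Borders use edge-replicated padding.
    """
    if window_w % 2 == 0 or window_h % 2 == 0:
        raise ValueError("census window dimensions must be odd")
    img = to_gray(image)
    h, w = img.shape
    if window_w > w or window_h > h:
        raise ValueError("census window larger than image")
    n_bits = window_w * window_h - 1
    if n_bits > 63:
        raise ValueError("census window too large for 64-bit packing")
    rw, rh = window_w // 2, window_h // 2
    padded = np.pad(img, ((rh, rh), (rw, rw)), mode="edge")
    out = np.zeros((h, w), dtype=np.uint64)
    bit = n_bits - 1
    for dy in range(-rh, rh + 1):
        for dx in range(-rw, rw + 1):
            if dy == 0 and dx == 0:
                continue
            neigh = padded[rh + dy:rh + dy + h, rw + dx:rw + dx + w]
            out |= (neigh < img).astype(np.uint64) << np.uint64(bit)
            bit -= 1
    return out


def _shifted_pairs(width: int, d: int, sign: int):
    """Column slices pairing ref(x) with other(x + sign*d) inside the image."""
    shift = sign * d
    if shift >= 0:
        sl_a = np.s_[:, : width - shift] if shift else np.s_[:, :]
        sl_b = np.s_[:, shift:]
    else:
        sl_a = np.s_[:, -shift:]
        sl_b = np.s_[:, : width + shift]
    return sl_a, sl_b


def _build_volume(cost_fn, shape, d_min, d_max, sign):
    h, w = shape
    vol = np.full((d_max - d_min + 1, h, w), SENTINEL)
    for i, d in enumerate(range(d_min, d_max + 1)):
        sl_a, sl_b = _shifted_pairs(w, d, sign)
        vol[i][sl_a] = cost_fn(sl_a, sl_b)
    return vol


def hamming_cost(census_l: np.ndarray, census_r: np.ndarray,
                 d_range: tuple[int, int], view: str = "left") -> CostVolume:
    """Hamming distance between census strings at each candidate disparity.

    Left reference compares census_l(x) with census_r(x - d); the right
    reference (census maps swapped by the caller) compares at x + d.
    """
    if census_l.shape != census_r.shape:
        raise ValueError("census maps must share a shape")
    d_min, d_max = d_range
    sign = -1 if view == "left" else +1
    ref, other = census_l, census_r

    def cost(sl_a, sl_b):
        return np.bitwise_count(ref[sl_a] ^ other[sl_b]).astype(np.float64)

    vol = _build_volume(cost, ref.shape, d_min, d_max, sign)
    return CostVolume(vol, d_min, d_max, view)


def ad_cost(image_l: np.ndarray, image_r: np.ndarray,
            d_range: tuple[int, int], view: str = "left") -> CostVolume:
    """Absolute intensity difference |I_ref(x) - I_other(x -/+ d)|."""
    a, b = to_gray(image_l), to_gray(image_r)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    d_min, d_max = d_range
    sign = -1 if view == "left" else +1

    def cost(sl_a, sl_b):
        return np.abs(a[sl_a] - b[sl_b])

    vol = _build_volume(cost, a.shape, d_min, d_max, sign)
    return CostVolume(vol, d_min, d_max, view)


def combine_ad_census(c_ad: CostVolume, c_census: CostVolume,
                      lambda_ad: float = DEFAULT_LAMBDA_AD,
                      lambda_census: float = DEFAULT_LAMBDA_CENSUS,
                      ) -> CostVolume:
    """Robust combination rho(c_census, l_census) + rho(c_ad, l_ad) in [0, 2]."""
    if lambda_ad <= 0 or lambda_census <= 0:
        raise ValueError("lambdas must be positive")
    if c_ad.costs.shape != c_census.costs.shape:
        raise ValueError("cost volumes must share shape and d_range")
    sentinels = ~np.isfinite(c_ad.costs) | ~np.isfinite(c_census.costs)
    with np.errstate(invalid="ignore"):
        combined = ((1.0 - np.exp(-c_census.costs / lambda_census)) +
                    (1.0 - np.exp(-c_ad.costs / lambda_ad)))
    combined[sentinels] = SENTINEL
    return CostVolume(combined, c_ad.d_min, c_ad.d_max, c_ad.view)


def aggregate_costs(volume: CostVolume, window: int = DEFAULT_AGG_WINDOW,
                    ) -> CostVolume:
    """Box-filter each disparity slice, excluding sentinel cells from means."""
    if window % 2 == 0 or window < 1:
        raise ValueError("aggregation window must be odd and positive")
    if window == 1:
        return CostVolume(volume.costs.copy(), volume.d_min, volume.d_max,
                          volume.view)
    finite = np.isfinite(volume.costs)
    filled = np.where(finite, volume.costs, 0.0)
    num = uniform_filter(filled, size=(1, window, window), mode="nearest")
    den = uniform_filter(finite.astype(np.float64),
                         size=(1, window, window), mode="nearest")
    out = np.full_like(volume.costs, SENTINEL)
    ok = den > 1e-12
    out[ok] = np.maximum(num[ok] / den[ok], 0.0)  # filter round-off guard
    out[~finite] = SENTINEL  # an out-of-view cell stays a sentinel
    return CostVolume(out, volume.d_min, volume.d_max, volume.view)


def wta_disparity(volume: CostVolume, subpixel: bool = True) -> DisparityMap:
    """Winner-take-all argmin over disparities, ties toward smaller d.

    With ``subpixel`` a parabola through the winner and its two neighbours
    refines d by -(c+ - c-) / (2 (c+ + c- - 2 c0)), clamped to +/-0.5; the
    refinement is skipped at range ends and next to sentinel costs.
    """
    costs = volume.costs
    n_disp = costs.shape[0]
    if subpixel and n_disp < 3:
        raise ValueError("subpixel refinement needs at least 3 disparities")
    finite_any = np.isfinite(costs).any(axis=0)
    idx = np.argmin(np.where(np.isfinite(costs), costs, np.inf), axis=0)
    values = (volume.d_min + idx).astype(np.float64)

    if subpixel:
        interior = (idx > 0) & (idx < n_disp - 1)
        yy, xx = np.nonzero(interior)
        i0 = idx[yy, xx]
        c0 = costs[i0, yy, xx]
        cm = costs[i0 - 1, yy, xx]
        cp = costs[i0 + 1, yy, xx]
        denom = cp + cm - 2 * c0
        ok = np.isfinite(cm) & np.isfinite(cp) & (denom > 1e-12)
        offset = np.zeros_like(c0)
        offset[ok] = np.clip(-(cp[ok] - cm[ok]) / (2 * denom[ok]), -0.5, 0.5)
        values[yy, xx] += offset

    values[~finite_any] = 0.0  # no admissible disparity at all
    return DisparityMap(values, volume.view)


def winning_cost(volume: CostVolume) -> np.ndarray:
    """Minimum (finite) cost per pixel; inf where every cell is a sentinel."""
    return np.min(np.where(np.isfinite(volume.costs), volume.costs, np.inf),
                  axis=0)


def match_stereo(pair, params: StereoParams | None = None,
                 ) -> tuple[DisparityMap, DisparityMap, CostVolume, CostVolume]:
    """Full AD-CENSUS pass with left and, mirrored, right reference.

    Images are matched in [0, 1]; lambda_ad, quoted on the 8-bit scale, is
    divided by 255 to act on the same scale as the AD costs.
    """
    if params is None:
        params = StereoParams()
    left, right = to_gray(pair.left), to_gray(pair.right)
    ww, wh = params.census_window
    cen_l = census_transform(left, ww, wh)
    cen_r = census_transform(right, ww, wh)
    d_range = (params.d_min, params.d_max)
    lam_ad = params.lambda_ad / 255.0

    out = {}
    for view, ref_c, oth_c, ref_i, oth_i in (
            ("left", cen_l, cen_r, left, right),
            ("right", cen_r, cen_l, right, left)):
        c_ham = hamming_cost(ref_c, oth_c, d_range, view)
        c_ad = ad_cost(ref_i, oth_i, d_range, view)
        comb = combine_ad_census(c_ad, c_ham, lam_ad, params.lambda_census)
        agg = aggregate_costs(comb, params.agg_window)
        out[view] = (wta_disparity(agg, params.subpixel), agg)
    return out["left"][0], out["right"][0], out["left"][1], out["right"][1]
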