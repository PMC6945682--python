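"""Confidence measures and proxy-label distillation.

Classical stereo output is dense but partly wrong (occlusions, low texture,
borders). Before it may supervise a network it is distilled: each confidence
measure vetoes pixels it deems unreliable, and the surviving sparse map is
the proxy label. Measures: left-right consistency (LRC), uniqueness
constraint (UC), distance to border (DB), average peak ratio (APKR), winner
margin (WM), and — for the stricter profile used to build proxy ground truth
at evaluation time — deviation from the windowed median.

Binary measures return {0,1}; APKR and WM are continuous with larger =
more confident and are thresholded at distillation time. All measures are
combined conjunctively: one veto removes the pixel. Distillation only ever
removes pixels; a retained value is copied verbatim from the input map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .stereo_core import CostVolume, DisparityMap, winning_cost

TRAINING_PROFILE = ("lrc", "uc", "db", "apkr", "wm")
RIGID_PROFILE = TRAINING_PROFILE + ("median",)


@dataclass
class ConfidenceMap:
    values: np.ndarray
    measure: str
    binary: bool


@dataclass
class ProxyLabel:
    """Sparse disparity map; zero marks a distilled-out (or invalid) pixel."""

    d_tilde: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.d_tilde != 0

    @property
    def n_p(self) -> int:
        return int(np.count_nonzero(self.d_tilde))


@dataclass
class DistillationParams:
    eps_lrc: float = 1.0
    db_margin: int | None = None  # None: use the stereo d_max
    thr_apkr: float = 1.5
    thr_wm: float = 0.02
    tau_med: float = 2.0
    med_window: int = 5
    use_median: bool = False

    def __post_init__(self) -> None:
        if (self.eps_lrc <= 0 or self.thr_apkr <= 0 or self.thr_wm <= 0
                or self.tau_med <= 0 or self.med_window < 1):
            raise ValueError("distillation thresholds must be positive")


def _sign(view: str) -> int:
    return -1 if view == "left" else +1


def lrc_check(d_l: DisparityMap, d_r: DisparityMap,
              eps_lrc: float = 1.0) -> ConfidenceMap:
    """Pass iff the other view's disparity agrees within eps at the match.

    The right map is sampled at the rounded matching column; a sample that
    leaves the image, or an invalid pixel in either map, fails.
    """
    dl, dr = d_l.values, d_r.values
    if dl.shape != dr.shape:
        raise ValueError("disparity maps must share a shape")
    h, w = dl.shape
    cols = np.arange(w)[None, :]
    target = np.round(cols + _sign(d_l.view) * dl).astype(int)
    inside = (target >= 0) & (target <= w - 1)
    t_safe = np.clip(target, 0, w - 1)
    rows = np.arange(h)[:, None]
    sampled = dr[rows, t_safe]
    ok = inside & (dl != 0) & (sampled != 0) & \
        (np.abs(dl - sampled) <= eps_lrc)
    return ConfidenceMap(ok.astype(np.uint8), "lrc", binary=True)


def uniqueness_mask(d_l: DisparityMap, volume_l: CostVolume) -> ConfidenceMap:
    """Pass iff no cheaper pixel of the row claims the same match column.

    Among all pixels of a row whose rounded match coordinate coincides, only
    the one with the lowest winning cost survives (leftmost on cost ties).
    """
    dl = d_l.values
    h, w = dl.shape
    wcost = winning_cost(volume_l)
    cols = np.arange(w)
    ok = np.zeros((h, w), dtype=np.uint8)
    for y in range(h):
        target = np.round(cols + _sign(d_l.view) * dl[y]).astype(int)
        valid = (target >= 0) & (target <= w - 1) & (dl[y] != 0) & \
            np.isfinite(wcost[y])
        order = np.lexsort((cols, wcost[y], target))
        order = order[valid[order]]
        t_sorted = target[order]
        first = np.ones(order.size, dtype=bool)
        first[1:] = t_sorted[1:] != t_sorted[:-1]
        ok[y, order[first]] = 1
    return ConfidenceMap(ok, "uc", binary=True)


def distance_to_border(shape: tuple[int, int], db_margin: int) -> ConfidenceMap:
    """Pass iff the Chebyshev distance to the nearest border >= margin."""
    h, w = shape
    if db_margin >= min(w, h) / 2:
        raise ValueError("db_margin must be < half the short image side")
    ys = np.minimum(np.arange(h), np.arange(h)[::-1])[:, None]
    xs = np.minimum(np.arange(w), np.arange(w)[::-1])[None, :]
    ok = (np.minimum(ys, xs) >= db_margin).astype(np.uint8)
    return ConfidenceMap(ok, "db", binary=True)


def _c1_c2(volume: CostVolume) -> tuple[np.ndarray, np.ndarray]:
    """Winning cost c1 and the best cost c2 at disparities not adjacent
    (|delta d| > 1) to the winner; c2 falls back to c1 when no such
    disparity has a finite cost."""
    costs = np.where(np.isfinite(volume.costs), volume.costs, np.inf)
    idx = np.argmin(costs, axis=0)
    c1 = np.take_along_axis(costs, idx[None], axis=0)[0]
    dgrid = np.arange(costs.shape[0])[:, None, None]
    non_adjacent = np.abs(dgrid - idx[None]) > 1
    c2 = np.min(np.where(non_adjacent, costs, np.inf), axis=0)
    c1 = np.where(np.isfinite(c1), c1, np.inf)
    c2 = np.where(np.isfinite(c2), c2, c1)
    # all-sentinel pixels: flat behaviour (minimum confidence)
    bad = ~np.isfinite(c1)
    c1[bad] = 1.0
    c2[bad] = 1.0
    return c1, c2


def apkr(volume: CostVolume, d_map: DisparityMap | None = None,
         window: int = 5) -> ConfidenceMap:
    """Average peak ratio: windowed mean of c2/c1 (>= 1, larger = better)."""
    if volume.costs.shape[0] < 4:
        raise ValueError("APKR needs at least 4 disparities")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    c1, c2 = _c1_c2(volume)
    ratio = c2 / np.maximum(c1, 1e-6)
    if window > 1:
        ratio = uniform_filter(ratio, size=window, mode="nearest")
    return ConfidenceMap(ratio, "apkr", binary=False)


def winner_margin(volume: CostVolume) -> ConfidenceMap:
    """Winner margin (c2 - c1) / sum of costs; zero-sum curves map to 0."""
    if volume.costs.shape[0] < 4:
        raise ValueError("WM needs at least 4 disparities")
    c1, c2 = _c1_c2(volume)
    finite = np.isfinite(volume.costs)
    total = np.where(finite, volume.costs, 0.0).sum(axis=0)
    wm = np.zeros_like(total)
    ok = total > 1e-12
    wm[ok] = (c2[ok] - c1[ok]) / total[ok]
    return ConfidenceMap(wm, "wm", binary=False)


def median_deviation(d_map: DisparityMap, med_window: int = 5,
                     tau_med: float = 2.0) -> ConfidenceMap:
    """Pass iff |d - windowed median of valid disparities| <= tau.

    Invalid (zero) pixels are left out of the median; windows with fewer
    than 3 valid pixels pass by default, and invalid centre pixels fail.
    """
    if med_window % 2 == 0:
        raise ValueError("median window must be odd")
    d = d_map.values
    h, w = d.shape
    r = med_window // 2
    padded = np.pad(np.where(d != 0, d, np.nan), r, constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded,
                                                   (med_window, med_window))
    flat = win.reshape(h, w, -1)
    n_valid = np.count_nonzero(~np.isnan(flat), axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(flat, axis=2)
    ok = (n_valid < 3) | (np.abs(d - med) <= tau_med)
    ok &= d != 0
    return ConfidenceMap(ok.astype(np.uint8), "median", binary=True)


def compute_confidence_maps(d_l: DisparityMap, d_r: DisparityMap,
                            volume_l: CostVolume,
                            params: DistillationParams,
                            profile: str = "training",
                            d_max: int | None = None,
                            apkr_window: int = 5) -> dict[str, ConfidenceMap]:
    """All confidence maps of a distillation profile, keyed by measure tag."""
    measures = {"training": TRAINING_PROFILE, "rigid": RIGID_PROFILE}[profile]
    margin = params.db_margin
    if margin is None:
        margin = volume_l.d_max if d_max is None else d_max
    maps = {
        "lrc": lrc_check(d_l, d_r, params.eps_lrc),
        "uc": uniqueness_mask(d_l, volume_l),
        "db": distance_to_border(d_l.values.shape, margin),
        "apkr": apkr(volume_l, d_l, apkr_window),
        "wm": winner_margin(volume_l),
    }
    if "median" in measures:
        maps["median"] = median_deviation(d_l, params.med_window,
                                          params.tau_med)
    return {k: maps[k] for k in measures}


def distill(d_l: DisparityMap, maps: dict[str, ConfidenceMap],
            params: DistillationParams) -> ProxyLabel:
    """Conjunction of all measures: one veto removes the pixel.

    Retained values are copied verbatim from d_l; APKR and WM are
    thresholded at params.thr_apkr / params.thr_wm, binary measures must
    equal 1. An empty support is legal but warned about.
    """
    keep = d_l.values != 0
    for tag, cmap in maps.items():
        if cmap.values.shape != d_l.values.shape:
            raise ValueError(f"confidence map {tag!r} shape mismatch")
        if cmap.binary:
            keep &= cmap.values.astype(bool)
        elif tag == "apkr":
            keep &= cmap.values >= params.thr_apkr
        elif tag == "wm":
            keep &= cmap.values >= params.thr_wm
        else:
            raise ValueError(f"unknown continuous measure {tag!r}")
    d_tilde = np.where(keep, d_l.values, 0.0)
    label = ProxyLabel(d_tilde)
    if label.n_p == 0:
        warnings.warn("distillation removed every pixel (empty support)",
                      stacklevel=2)
    return label


def distill_proxy(d_l: DisparityMap, d_r: DisparityMap, volume_l: CostVolume,
                  params: DistillationParams | None = None,
                  profile: str = "training") -> ProxyLabel:
    """Convenience wrapper: confidence maps + distillation in one call."""
    if params is None:
        params = DistillationParams(use_median=(profile == "rigid"))
    if params.use_median and profile == "training":
        profile = "rigid"
    maps = compute_confidence_maps(d_l, d_r, volume_l, params, profile)
    return distill(d_l, maps, params)
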