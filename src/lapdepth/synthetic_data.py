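"""Synthetic rectified stereo scenes with known dense disparity.

Real laparoscopic stereo footage has no ground truth, which is exactly why
the proxy-label pipeline exists; to test that pipeline end to end we render
rectified pairs from a smooth, tissue-like disparity surface and a textured
intensity field, so every downstream stage (classical matching, confidence
distillation, network training, metric evaluation) can be scored against a
known answer.

Conventions (global for the whole package): disparity d >= 0 and the right-
view column matching left column x is x - d. A left pixel is occluded when a
left pixel of larger disparity projects to the same rounded right column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from . import io as lio
from .geometry_eval import CameraModel

#: Disparity sign convention: right column = left column + DISPARITY_SIGN * d.
DISPARITY_SIGN = -1

# Default camera for synthetic scenes: ~50-300 mm working depth for
# disparities in [2, 12] px, typical of a laparoscope at 4 mm baseline.
DEFAULT_CAMERA = CameraModel(fx=150.0, fy=150.0, cx=64.0, cy=64.0, baseline=4.0)


@dataclass
class StereoPair:
    """A rectified image pair sharing one camera model."""

    left: np.ndarray
    right: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape[-2], self.left.shape[-1]


@dataclass
class GroundTruthScene:
    """A rendered stereo scene with dense ground-truth disparity."""

    texture: np.ndarray
    gt_disparity: np.ndarray
    validity: np.ndarray
    camera: CameraModel
    seed: int
    pair: StereoPair


def make_disparity_field(width: int, height: int, d_min: float, d_max: float,
                         smoothness: float = 0.15, seed: int = 0) -> np.ndarray:
    """Smooth non-negative disparity surface in [d_min, d_max].

    ``smoothness`` sets the Gaussian correlation length as a fraction of the
    short image side; as it grows the field flattens toward the mid-range
    value (d_min + d_max) / 2.
    """
    if width < 16 or height < 16:
        raise ValueError("image must be at least 16x16")
    if not (0 <= d_min < d_max < width):
        raise ValueError(f"need 0 <= d_min < d_max < width, got [{d_min}, {d_max}]")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    mid = 0.5 * (d_min + d_max)
    # beyond ~4 image sides of correlation the field is flat anyway
    if not np.isfinite(smoothness) or smoothness * min(width, height) > \
            4 * min(width, height):
        return np.full((height, width), mid)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    field = gaussian_filter(noise, sigma=smoothness * min(width, height),
                            mode="reflect")
    std = field.std()
    if std < 1e-8:  # smoothing annihilated all variation
        return np.full((height, width), mid)
    field = (field - field.mean()) / std
    half = 0.5 * (d_max - d_min)
    return np.clip(mid + half * field / 2.0, d_min, d_max)


def make_texture(width: int, height: int, octaves: int = 4,
                 seed: int = 0) -> np.ndarray:
    """Multi-octave band-limited noise texture in [0, 1].

    Octave o contributes Gaussian-filtered noise at correlation length
    4 / 2**o px with amplitude 0.55**o, which keeps enough local contrast
    for census matching to be well-posed (7x7 window std above 0.01).
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if width < 16 or height < 16:
        raise ValueError("image must be at least 16x16")
    rng = np.random.default_rng(seed)
    tex = np.zeros((height, width))
    for o in range(octaves):
        layer = gaussian_filter(rng.standard_normal((height, width)),
                                sigma=4.0 / 2 ** o, mode="reflect")
        layer /= max(layer.std(), 1e-12)
        tex += 0.55 ** o * layer
    tex -= tex.min()
    tex /= max(tex.max(), 1e-12)
    return tex


def occlusion_mask(gt_disparity: np.ndarray) -> np.ndarray:
    """Boolean mask of left pixels occluded in the right view.

    A pixel is occluded iff another pixel of the same row with strictly
    larger disparity lands on the same rounded right-view column.
    """
    h, w = gt_disparity.shape
    occluded = np.zeros((h, w), dtype=bool)
    cols = np.arange(w)
    for y in range(h):
        target = np.round(cols + DISPARITY_SIGN * gt_disparity[y]).astype(int)
        order = np.lexsort((-gt_disparity[y], target))  # per target, big d first
        t_sorted = target[order]
        first = np.ones(w, dtype=bool)
        first[1:] = t_sorted[1:] != t_sorted[:-1]
        occluded[y, order[~first]] = True
    return occluded


def render_stereo_pair(scene_texture: np.ndarray, gt_disparity: np.ndarray,
                       noise_sigma: float = 0.0, seed: int = 0,
                       ) -> tuple[StereoPair, np.ndarray]:
    """Render the right view of a textured surface seen with parallax.

    The left image is the texture itself. The right image is built per row by
    inverting the forward map x -> x - d(x): right column x_r shows the
    texture at the left coordinate that projects onto it (the nearest surface
    when several do). The validity mask is 0 where the right-view coordinate
    leaves the image or the pixel is occluded.
    """
    tex = np.asarray(scene_texture, dtype=np.float64)
    d = np.asarray(gt_disparity, dtype=np.float64)
    if tex.shape != d.shape:
        raise ValueError("texture and disparity shapes differ")
    h, w = tex.shape
    if np.any(d < 0) or np.any(d >= w):
        raise ValueError("disparity must lie in [0, width)")

    cols = np.arange(w, dtype=np.float64)
    right = np.empty_like(tex)
    for y in range(h):
        target = cols + DISPARITY_SIGN * d[y]
        order = np.argsort(target, kind="stable")
        # interp needs increasing abscissae; occlusion folds are resolved by
        # the z-buffer semantics of the occlusion mask, not the image itself
        src = np.interp(cols, target[order], cols[order])
        x0 = np.clip(np.floor(src).astype(int), 0, w - 2)
        frac = np.clip(src - x0, 0.0, 1.0)
        right[y] = (1 - frac) * tex[y, x0] + frac * tex[y, x0 + 1]

    target_all = cols[None, :] + DISPARITY_SIGN * d
    validity = ((target_all >= 0) & (target_all <= w - 1) &
                ~occlusion_mask(d)).astype(np.uint8)

    left = tex.copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        left = np.clip(left + rng.normal(0, noise_sigma, left.shape), 0, 1)
        right = np.clip(right + rng.normal(0, noise_sigma, right.shape), 0, 1)
    return StereoPair(left=left, right=right), validity


def make_scene(width: int = 128, height: int = 128, d_min: float = 2.0,
               d_max: float = 12.0, smoothness: float = 0.15,
               texture_octaves: int = 4, noise_sigma: float = 0.0,
               seed: int = 0, camera: CameraModel | None = None,
               ) -> GroundTruthScene:
    """Generate a full synthetic scene (texture, disparity, rendered pair)."""
    rng = np.random.default_rng(seed)
    s_disp, s_tex, s_noise = (int(x) for x in
                              rng.integers(0, 2 ** 31 - 1, size=3))
    disparity = make_disparity_field(width, height, d_min, d_max,
                                     smoothness, seed=s_disp)
    texture = make_texture(width, height, texture_octaves, seed=s_tex)
    pair, validity = render_stereo_pair(texture, disparity, noise_sigma,
                                        seed=s_noise)
    if camera is None:
        camera = CameraModel(fx=150.0, fy=150.0, cx=width / 2.0,
                             cy=height / 2.0, baseline=4.0)
    return GroundTruthScene(texture=texture, gt_disparity=disparity,
                            validity=validity, camera=camera, seed=seed,
                            pair=pair)


def write_scene(scene: GroundTruthScene, out_dir: str | Path) -> None:
    """Write a scene in the directory layout the CLI stages read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lio.write_image(out / "left.png", scene.pair.left)
    lio.write_image(out / "right.png", scene.pair.right)
    lio.write_pfm(out / "gt_disparity.pfm", scene.gt_disparity)
    lio.write_disparity_png(out / "gt_disparity.png", scene.gt_disparity)
    lio.write_image(out / "validity.png", scene.validity.astype(np.float64))
    lio.write_camera_json(out / "camera.json", scene.camera)
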