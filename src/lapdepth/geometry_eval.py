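"""Disparity-to-depth conversion, point clouds, and the evaluation protocol.

Depth follows rectified-stereo triangulation D = fx * baseline / d (mm for a
baseline in mm); pixels back-project through the pinhole model to 3-D points.
Accuracy is reported as per-frame MAE and RMSE over the non-zero ground
truth pixels, frames with fewer than ``min_points`` (default 10,000) valid
ground-truth points are excluded to curb per-point randomness, and a
disparity threshold removes far background pixels before scoring. Aggregates
are mean +/- population standard deviation over included frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MIN_POINTS = 10_000


@dataclass
class CameraModel:
    """Pinhole camera of a rectified pair; baseline in mm, the rest in px."""

    fx: float
    fy: float
    cx: float
    cy: float
    baseline: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0 or self.baseline <= 0:
            raise ValueError("fx, fy and baseline must be positive")


@dataclass
class DepthMap:
    """Per-pixel depth in mm; 0 marks an invalid pixel."""

    values: np.ndarray


@dataclass
class FrameResult:
    index: int
    n: int
    mae: float
    rmse: float
    included: bool


@dataclass
class EvalResult:
    frames: list[FrameResult] = field(default_factory=list)
    mae_mean: float = np.nan
    mae_std: float = np.nan
    rmse_mean: float = np.nan
    rmse_std: float = np.nan

    @property
    def excluded(self) -> list[int]:
        return [f.index for f in self.frames if not f.included]


def disparity_to_depth(d_map, camera: CameraModel) -> DepthMap:
    """D = fx * baseline / d; non-positive disparities map to invalid 0."""
    d = np.asarray(getattr(d_map, "values", d_map), dtype=np.float64)
    depth = np.zeros_like(d)
    ok = d > 0
    depth[ok] = camera.fx * camera.baseline / d[ok]
    return DepthMap(depth)


def depth_to_pointcloud(depth, camera: CameraModel,
                        colors: np.ndarray | None = None):
    """Back-project valid depth pixels to (X, Y, Z) in mm.

    X = (u - cx) D / fx, Y = (v - cy) D / fy, Z = D. Returns an N x 3 array
    (and, when an image is supplied, the N x 3 colours of the same pixels).
    """
    dm = np.asarray(getattr(depth, "values", depth), dtype=np.float64)
    h, w = dm.shape
    vs, us = np.nonzero(dm > 0)
    z = dm[vs, us]
    pts = np.column_stack([(us - camera.cx) * z / camera.fx,
                           (vs - camera.cy) * z / camera.fy,
                           z])
    if colors is None:
        return pts
    img = np.asarray(colors, dtype=np.float64)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    return pts, img[vs, us]


def project_points(points: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Forward projection (u, v, D) of 3-D points; the round-trip inverse of
    depth_to_pointcloud."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    z = pts[:, 2]
    return np.column_stack([pts[:, 0] * camera.fx / z + camera.cx,
                            pts[:, 1] * camera.fy / z + camera.cy,
                            z])


def _residuals(pred, gt) -> np.ndarray:
    p = np.asarray(getattr(pred, "values", pred), dtype=np.float64)
    g = np.asarray(getattr(gt, "values", gt), dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth shapes differ")
    mask = g != 0
    if not mask.any():
        raise ValueError("ground truth has no non-zero pixels")
    return p[mask] - g[mask]


def mae(pred, gt) -> float:
    """Mean absolute depth error (mm) over non-zero ground-truth pixels."""
    return float(np.mean(np.abs(_residuals(pred, gt))))


def rmse(pred, gt) -> float:
    """Root-mean-square depth error (mm) over non-zero ground-truth pixels."""
    return float(np.sqrt(np.mean(_residuals(pred, gt) ** 2)))


def filter_frames(gt_frames, min_points: int = DEFAULT_MIN_POINTS,
                  ) -> tuple[list[int], list[int]]:
    """Split frame indices into (included, excluded) by the support-size
    rule: a frame is excluded iff its non-zero ground-truth count < min_points
    (strictly less; a frame at exactly min_points is kept)."""
    included, excluded = [], []
    for i, gt in enumerate(gt_frames):
        g = np.asarray(getattr(gt, "values", gt))
        (included if np.count_nonzero(g) >= min_points else excluded).append(i)
    return included, excluded


def background_threshold(d_map: np.ndarray, tau_bg: float) -> np.ndarray:
    """Invalidate background pixels: disparities below tau_bg (far scene
    content) are set to 0."""
    if tau_bg < 0:
        raise ValueError("tau_bg must be non-negative")
    d = np.asarray(getattr(d_map, "values", d_map), dtype=np.float64)
    return np.where(d >= tau_bg, d, 0.0)


def evaluate_dataset(pred_frames, gt_frames, camera: CameraModel,
                     min_points: int = DEFAULT_MIN_POINTS,
                     tau_bg: float = 0.0, sample_std: bool = False,
                     ) -> EvalResult:
    """Per-frame protocol: background-threshold the ground-truth disparity,
    exclude small frames, convert both maps to depth, and score MAE/RMSE.

    ``pred_frames`` and ``gt_frames`` hold per-frame disparity maps in px.
    Aggregates are mean +/- population std (``sample_std`` switches to the
    n-1 normalisation).
    """
    if len(pred_frames) != len(gt_frames):
        raise ValueError("prediction and ground-truth frame counts differ")
    gt_thr = [background_threshold(g, tau_bg) for g in gt_frames]
    included, _ = filter_frames(gt_thr, min_points)
    result = EvalResult()
    for i, (pred, gt) in enumerate(zip(pred_frames, gt_thr)):
        n = int(np.count_nonzero(gt))
        if i not in included:
            result.frames.append(FrameResult(i, n, np.nan, np.nan, False))
            continue
        pred_depth = disparity_to_depth(pred, camera)
        gt_depth = disparity_to_depth(gt, camera)
        result.frames.append(FrameResult(i, n, mae(pred_depth, gt_depth),
                                         rmse(pred_depth, gt_depth), True))
    scored = [f for f in result.frames if f.included]
    if not scored:
        raise ValueError("every frame was excluded; nothing to aggregate")
    ddof = 1 if sample_std else 0
    maes = np.array([f.mae for f in scored])
    rmses = np.array([f.rmse for f in scored])
    result.mae_mean = float(maes.mean())
    result.mae_std = float(maes.std(ddof=ddof)) if maes.size > ddof else 0.0
    result.rmse_mean = float(rmses.mean())
    result.rmse_std = float(rmses.std(ddof=ddof)) if rmses.size > ddof else 0.0
    return result


def eval_result_rows(result: EvalResult) -> list[dict]:
    """CSV-ready rows (one per frame plus a summary row)."""
    rows = [dict(frame=f.index, n=f.n, mae=f.mae, rmse=f.rmse,
                 included=int(f.included)) for f in result.frames]
    rows.append(dict(frame="summary",
                     n=sum(f.n for f in result.frames if f.included),
                     mae=f"{result.mae_mean:.4f}+/-{result.mae_std:.4f}",
                     rmse=f"{result.rmse_mean:.4f}+/-{result.rmse_std:.4f}",
                     included=len([f for f in result.frames if f.included])))
    return rows
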