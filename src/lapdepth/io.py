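"""File I/O for images, disparity maps, cameras and point clouds.

Disparity maps travel in two interchangeable on-disk forms: PFM (float32,
lossless) and 16-bit PNG at a fixed scale of 256 (stored value =
round(256 * d), so the PNG form quantises to 1/256 px). Zero encodes an
invalid pixel in both forms.
"""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import numpy as np
import trimesh

DISPARITY_PNG_SCALE = 256.0


# ---------------------------------------------------------------- images

def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image as float in [0, 1]; grayscale images come back 2-D."""
    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return arr


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def to_gray(image: np.ndarray) -> np.ndarray:
    """Channel-mean of an H×W or H×W×C image."""
    image = np.asarray(image, dtype=np.float64)
    return image.mean(axis=2) if image.ndim == 3 else image


# ------------------------------------------------------------- disparity

def write_disparity_png(path: str | os.PathLike, disparity: np.ndarray) -> None:
    d = np.asarray(disparity, dtype=np.float64)
    enc = np.round(d * DISPARITY_PNG_SCALE)
    if np.any(enc < 0) or np.any(enc > 65535):
        raise ValueError("disparity out of range for 16-bit PNG at scale 256")
    iio.imwrite(path, enc.astype(np.uint16))


def read_disparity_png(path: str | os.PathLike) -> np.ndarray:
    enc = iio.imread(path)
    return enc.astype(np.float64) / DISPARITY_PNG_SCALE


# ------------------------------------------------------------------ PFM
# PFM is the float stereo-map interchange format: a 'Pf' header, width and
# height, a scale whose sign encodes endianness, then rows bottom-to-top.

def write_pfm(path: str | os.PathLike, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("PFM writer expects a 2-D map")
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{data.shape[1]} {data.shape[0]}\n".encode("ascii"))
        fh.write(b"-1.0\n")  # negative scale = little-endian
        fh.write(np.flipud(data).astype("<f4").tobytes())


def read_pfm(path: str | os.PathLike) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.readline().strip() not in (b"Pf", b"PF"):
            raise ValueError("not a PFM file")
        width, height = map(int, fh.readline().split())
        scale = float(fh.readline())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(fh.read(width * height * 4), dtype=dtype)
    return np.flipud(data.reshape(height, width)).astype(np.float64)


# --------------------------------------------------------------- camera

def write_camera_json(path: str | os.PathLike, camera) -> None:
    payload = {
        "fx": camera.fx, "fy": camera.fy,
        "cx": camera.cx, "cy": camera.cy,
        "baseline_mm": camera.baseline,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_camera_json(path: str | os.PathLike):
    from .geometry_eval import CameraModel

    with open(path) as fh:
        d = json.load(fh)
    return CameraModel(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                       baseline=d["baseline_mm"])


# ------------------------------------------------------------------ PLY

def write_ply(path: str | os.PathLike, points: np.ndarray,
              colors: np.ndarray | None = None) -> None:
    """Write an N×3 point cloud as ASCII PLY (colors: N×3 floats in [0,1])."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    kwargs = {}
    if colors is not None:
        rgb = np.clip(np.asarray(colors, dtype=np.float64).reshape(-1, 3), 0, 1)
        kwargs["colors"] = (rgb * 255).astype(np.uint8)
    cloud = trimesh.PointCloud(points, **kwargs)
    with open(path, "wb") as fh:
        fh.write(cloud.export(file_type="ply", encoding="ascii"))
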