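"""Readers and writers for every on-disk artifact the pipeline touches.

Formats: 16-bit grayscale PNG for absolute depth (millimeters, 0 = invalid),
32-bit float TIFF for relative depth, 8-bit PNG for color, 8-bit paletted PNG
for instance masks, flat YAML/JSON for camera intrinsics, and binary
little-endian PLY for point clouds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
import yaml
from PIL import Image

from .types import CameraIntrinsics, CaptureBundle, DepthMap, PointCloud, TreeMask

# ---------------------------------------------------------------------------
# depth rasters


def read_depth_png(path, kind: str = "absolute") -> DepthMap:
    """Read an absolute depth map from a single-channel 16-bit PNG.

    Pixel values are millimeters; zero pixels are marked invalid.  For
    ``kind="relative"`` use :func:`read_depth_tiff` instead (relative maps are
    stored as float TIFF so the alignment fit is not quantized).
    """
    if kind != "absolute":
        raise ValueError("PNG depth maps are absolute; relative maps use TIFF")
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("I", "I;16", "I;16B"):
            raise ValueError(f"{path}: expected a single-channel 16-bit PNG, got mode {im.mode}")
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: depth PNG must be single-channel")
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError(f"{path}: values outside the 16-bit range")
    return DepthMap(values=arr.astype(np.uint16), kind="absolute")


def write_depth_png(depth, path) -> None:
    """Write absolute depth (mm) to 16-bit PNG; invalid pixels become 0."""
    if isinstance(depth, DepthMap):
        if depth.kind != "absolute":
            raise ValueError("only absolute depth can be written as 16-bit PNG")
        values = np.where(depth.valid, depth.values, 0)
    else:
        values = np.asarray(depth)
    values = np.asarray(np.rint(values), dtype=np.int64)
    if values.min() < 0 or values.max() > 65535:
        raise ValueError("depth values outside the 16-bit range")
    im = Image.fromarray(values.astype(np.uint16))
    im.save(Path(path), format="PNG")


def read_depth_tiff(path) -> DepthMap:
    """Read a relative (unitless) depth map from a float TIFF."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: relative depth TIFF must be single-channel")
    return DepthMap(values=arr.astype(np.float32), kind="relative")


def write_depth_tiff(depth: DepthMap, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(depth.values, dtype=np.float32))


# ---------------------------------------------------------------------------
# color images and masks


def read_rgb_png(path) -> np.ndarray:
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("RGB"))
    return arr


def write_rgb_png(rgb: np.ndarray, path) -> None:
    rgb = np.asarray(rgb, dtype=np.uint8)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an HxWx3 8-bit raster")
    Image.fromarray(rgb, mode="RGB").save(Path(path), format="PNG")


# distinct palette entries for up to 255 instances; index 0 = background
def _instance_palette() -> list:
    rng = np.random.default_rng(12345)
    pal = [0, 0, 0]
    for _ in range(255):
        pal.extend(int(c) for c in rng.integers(40, 256, size=3))
    return pal


def read_mask_png(path) -> TreeMask:
    """Read an instance mask from an 8-bit paletted (or grayscale) PNG."""
    with Image.open(Path(path)) as im:
        if im.mode not in ("P", "L"):
            raise ValueError(f"{path}: mask PNG must be paletted or grayscale")
        arr = np.asarray(im, dtype=np.int32)
    return TreeMask(labels=arr)


def write_mask_png(mask: TreeMask, path) -> None:
    labels = np.asarray(mask.labels)
    if labels.max(initial=0) > 255:
        raise ValueError("paletted mask supports at most 255 instances")
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    im.putpalette(_instance_palette())
    im.save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# intrinsics


def read_intrinsics(path) -> CameraIntrinsics:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    missing = {"fx", "fy", "cx", "cy", "width", "height"} - set(data)
    if missing:
        raise ValueError(f"{path}: intrinsics missing keys {sorted(missing)}")
    return CameraIntrinsics.from_dict(data)


def write_intrinsics(K: CameraIntrinsics, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(K.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(K.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# PLY point clouds (binary little-endian, float32 xyz + uchar rgb)

_PLY_HEADER = """ply
format binary_little_endian 1.0
element vertex {n}
property float x
property float y
property float z
property uchar red
property uchar green
property uchar blue
end_header
"""


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a colored point cloud as binary little-endian PLY (meters)."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    colors = cloud.colors
    if colors is None:
        colors = np.full((len(cloud), 3), 255, dtype=np.uint8)
    rec = np.empty(len(cloud), dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                                      ("red", "u1"), ("green", "u1"), ("blue", "u1")])
    pts = cloud.points.astype("<f4")
    rec["x"], rec["y"], rec["z"] = pts[:, 0], pts[:, 1], pts[:, 2]
    cols = np.asarray(colors, dtype=np.uint8)
    rec["red"], rec["green"], rec["blue"] = cols[:, 0], cols[:, 1], cols[:, 2]
    with open(Path(path), "wb") as fh:
        fh.write(_PLY_HEADER.format(n=len(cloud)).encode("ascii"))
        fh.write(rec.tobytes())


def read_point_cloud(path) -> PointCloud:
    """Read the PLY layout produced by :func:`write_point_cloud`."""
    with open(Path(path), "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode("ascii").strip()
            header.append(line)
            if line == "end_header":
                break
        if header[0] != "ply" or "format binary_little_endian 1.0" not in header[1]:
            raise ValueError(f"{path}: not a binary little-endian PLY")
        n = None
        for line in header:
            if line.startswith("element vertex"):
                n = int(line.split()[-1])
        if n is None:
            raise ValueError(f"{path}: no vertex element in header")
        rec = np.frombuffer(fh.read(), dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                                              ("red", "u1"), ("green", "u1"), ("blue", "u1")],
                            count=n)
    points = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    colors = np.stack([rec["red"], rec["green"], rec["blue"]], axis=1)
    return PointCloud(points=points, colors=colors)


# ---------------------------------------------------------------------------
# capture bundles

RGB_NAME = "rgb.png"
DEPTH_ABS_NAME = "depth_abs.png"
DEPTH_REL_NAME = "depth_rel.tiff"
MASK_NAME = "mask.png"


def _find_intrinsics(dir: Path) -> Path:
    for name in ("intrinsics.yaml", "intrinsics.yml", "intrinsics.json"):
        p = dir / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{dir}: no intrinsics.(yaml|json) found")


def load_bundle(dir) -> CaptureBundle:
    """Load a capture bundle directory (rgb + absolute depth + intrinsics,
    optional relative depth)."""
    dir = Path(dir)
    rgb_path = dir / RGB_NAME
    abs_path = dir / DEPTH_ABS_NAME
    for p in (rgb_path, abs_path):
        if not p.exists():
            raise FileNotFoundError(f"bundle missing {p.name} in {dir}")
    rgb = read_rgb_png(rgb_path)
    absolute = read_depth_png(abs_path)
    K = read_intrinsics(_find_intrinsics(dir))
    rel_path = dir / DEPTH_REL_NAME
    relative = read_depth_tiff(rel_path) if rel_path.exists() else None
    return CaptureBundle(rgb=rgb, absolute_depth=absolute,
                         relative_depth=relative, intrinsics=K)


def save_bundle(dir, rgb: np.ndarray, absolute: DepthMap,
                K: CameraIntrinsics, relative: Optional[DepthMap] = None,
                mask: Optional[TreeMask] = None) -> Path:
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    write_rgb_png(rgb, dir / RGB_NAME)
    write_depth_png(absolute, dir / DEPTH_ABS_NAME)
    write_intrinsics(K, dir / "intrinsics.yaml")
    if relative is not None:
        write_depth_tiff(relative, dir / DEPTH_REL_NAME)
    if mask is not None:
        write_mask_png(mask, dir / MASK_NAME)
    return dir
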