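"""Metric 3D reconstruction from depth + color + intrinsics.

Back-projection follows the pinhole model with depth d in millimeters and a
mm-per-meter ``scale`` (default 1000):

    z = -d / scale
    x = -(u - cx) * z / fx
    y = -(v - cy) * z / fy

so all points lie in front of the camera at negative z and tree height is the
Y-extent of the cloud.  The x-axis sign convention is immaterial for
axis-aligned extents and is configurable.

Per-tree clouds are cut out by the segmentation mask (each point remembers
its source pixel) and denoised with a single-pass radius outlier filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .types import CameraIntrinsics, DepthMap, PointCloud, TreeMask

DEFAULT_SCALE_MM_PER_M = 1000.0


@dataclass(frozen=True)
class RadiusFilterParams:
    """Radius outlier removal: keep points with enough close neighbors."""

    radius: float = 1.5          # meters
    min_neighbors: int = 10      # neighbor count threshold
    count_self: bool = False     # include the query point in its own count

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")


def backproject(depth: DepthMap, rgb=None, mask: TreeMask = None,
                K: CameraIntrinsics = None,
                scale: float = DEFAULT_SCALE_MM_PER_M,
                x_sign: float = -1.0) -> PointCloud:
    """Back-project every valid depth pixel into a metric point cloud.

    Parameters
    ----------
    depth : absolute DepthMap (millimeters).
    rgb : optional HxWx3 color raster; colors copied per point.
    mask : optional TreeMask; instance labels copied per point.
    K : camera intrinsics (required).
    scale : millimeters per meter (1000 converts mm depth to meter coordinates).
    x_sign : sign convention for the x equation, +/-1; extents are invariant.
    """
    if K is None:
        raise ValueError("camera intrinsics are required")
    if depth.kind != "absolute":
        raise ValueError("back-projection needs an absolute (metric) depth map")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if x_sign not in (-1.0, 1.0, -1, 1):
        raise ValueError("x_sign must be +1 or -1")
    h, w = depth.shape
    if (h, w) != (K.height, K.width):
        raise ValueError("depth shape does not match intrinsics")
    valid = depth.valid
    if not valid.any():
        raise ValueError("depth map has no valid pixels")
    # raster order (top-left to bottom-right) keeps pixel_index deterministic
    v_idx, u_idx = np.nonzero(valid)
    d = np.asarray(depth.values, dtype=np.float64)[v_idx, u_idx]
    z = -d / scale
    x = x_sign * (u_idx - K.cx) * z / K.fx
    y = -(v_idx - K.cy) * z / K.fy
    points = np.stack([x, y, z], axis=1)
    colors = None if rgb is None else np.asarray(rgb, dtype=np.uint8)[v_idx, u_idx]
    labels = None if mask is None else np.asarray(mask.labels)[v_idx, u_idx]
    return PointCloud(points=points, colors=colors, labels=labels,
                      pixel_index=np.stack([u_idx, v_idx], axis=1))


def reproject(cloud: PointCloud, K: CameraIntrinsics,
              scale: float = DEFAULT_SCALE_MM_PER_M,
              x_sign: float = -1.0) -> tuple:
    """Invert :func:`backproject`: recover (u, v, d_mm) for every point."""
    x, y, z = cloud.points.T
    if np.any(z >= 0):
        raise ValueError("points must lie in front of the camera (z < 0)")
    d = -z * scale
    u = x_sign * x * K.fx / z + K.cx
    v = -y * K.fy / z + K.cy
    return u, v, d


def split_by_label(cloud: PointCloud) -> dict:
    """Partition the cloud by instance label; background (0) is dropped."""
    if cloud.labels is None:
        raise ValueError("cloud carries no instance labels")
    labels = np.asarray(cloud.labels)
    out = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        out[int(k)] = cloud.select(labels == k)
    return out


def radius_filter(cloud: PointCloud,
                  params: RadiusFilterParams = RadiusFilterParams()) -> PointCloud:
    """Single-pass radius outlier removal.

    A point survives iff the number of other points within Euclidean distance
    ``radius`` is at least ``min_neighbors`` (the point itself is excluded
    from its own count unless ``count_self``).  Survivor order is preserved.
    The pass is applied once, not iterated to a fixed point.
    """
    n = len(cloud)
    if n == 0:
        return cloud
    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, r=params.radius,
                                   return_length=True)
    if not params.count_self:
        counts = counts - 1  # query_ball_point includes the point itself
    keep = counts >= params.min_neighbors
    return cloud.select(keep)
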