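"""Core domain containers shared by every pipeline stage.

Conventions
-----------
* Absolute depth is stored in millimeters as a float or uint16 raster; a value
  of 0 means "no measurement" (depth-from-motion maps have holes).
* Relative depth is unitless and only meaningful up to an affine transform
  ``A = S * R + D``.
* Point clouds are metric (meters) in the camera frame: the camera looks down
  the −Z axis, +X right, +Y toward the image bottom (so tree height is a
  Y-extent regardless of which way "up" points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DEPTH_MM_MAX = 65535.0  # sensor-representable range, millimeters


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters in pixel units."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def to_dict(self) -> dict:
        return {
            "fx": float(self.fx), "fy": float(self.fy),
            "cx": float(self.cx), "cy": float(self.cy),
            "width": int(self.width), "height": int(self.height),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(fx=float(d["fx"]), fy=float(d["fy"]), cx=float(d["cx"]),
                   cy=float(d["cy"]), width=int(d["width"]), height=int(d["height"]))


@dataclass
class DepthMap:
    """Per-pixel depth raster with an explicit validity mask.

    ``kind`` is "absolute" (millimeters) or "relative" (unitless affine).
    For absolute maps a value of exactly 0 is always invalid.
    """

    values: np.ndarray
    kind: str
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown depth kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("depth raster must be 2-D")
        if self.valid is None:
            if self.kind == "absolute":
                self.valid = self.values > 0
            else:
                self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values")
            if self.kind == "absolute":
                self.valid = self.valid & (self.values > 0)
        if self.kind == "absolute":
            v = np.asarray(self.values, dtype=float)[self.valid]
            if v.size and (v.min() < 0 or v.max() > DEPTH_MM_MAX):
                raise ValueError("absolute depth outside [0, 65535] mm")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class TreeMask:
    """Instance labels: 0 = background, k = tree k (k = 1..n_instances)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_instances(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple:
        return self.labels.shape


@dataclass
class CaptureBundle:
    """One capture: color image, absolute depth, optional relative depth."""

    rgb: np.ndarray
    absolute_depth: DepthMap
    intrinsics: CameraIntrinsics
    relative_depth: Optional[DepthMap] = None

    def __post_init__(self) -> None:
        h, w = self.rgb.shape[:2]
        if (self.intrinsics.height, self.intrinsics.width) != (h, w):
            raise ValueError(
                f"intrinsics {self.intrinsics.width}x{self.intrinsics.height} "
                f"do not match rasters {w}x{h}")
        for m in (self.absolute_depth, self.relative_depth):
            if m is not None and m.shape != (h, w):
                raise ValueError("raster shapes inconsistent within bundle")


@dataclass
class PointCloud:
    """Metric point cloud with per-point color, instance label and source pixel."""

    points: np.ndarray                # (N, 3) float, meters
    colors: Optional[np.ndarray] = None       # (N, 3) uint8
    labels: Optional[np.ndarray] = None        # (N,) int instance ids
    pixel_index: Optional[np.ndarray] = None   # (N, 2) source (u, v)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        n = len(self.points)
        for name in ("colors", "labels", "pixel_index"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != n:
                    raise ValueError(f"{name} length {len(arr)} != {n} points")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, idx: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index array, order preserved."""
        return PointCloud(
            points=self.points[idx],
            colors=None if self.colors is None else self.colors[idx],
            labels=None if self.labels is None else self.labels[idx],
            pixel_index=None if self.pixel_index is None else self.pixel_index[idx],
        )


@dataclass(frozen=True)
class AxisAlignedBox:
    min_corner: tuple
    max_corner: tuple

    def __post_init__(self) -> None:
        if any(a > b for a, b in zip(self.min_corner, self.max_corner)):
            raise ValueError("box min must be <= max componentwise")

    def extent(self) -> np.ndarray:
        return np.asarray(self.max_corner) - np.asarray(self.min_corner)


@dataclass
class TreeMeasurement:
    tree_id: int
    height_m: float
    n_points: int = 0
    true_height_m: Optional[float] = None
    shooting_distance_m: Optional[float] = None
    relative_error_pct: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.true_height_m is not None and self.relative_error_pct is None:
            from .measurement import relative_error
            self.relative_error_pct = relative_error(self.true_height_m, self.height_m)
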