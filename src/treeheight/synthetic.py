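"""Procedural RGB-D tree scenes with exact ground truth.

Scenes contain cylinder-trunk + ellipsoid-crown trees standing on a ground
plane, viewed by an upright pinhole camera 1.5 m above the ground looking
along -Z.  Per-pixel z-depth (millimeters), an instance mask and the designed
tree heights are returned exactly, so every pipeline stage — alignment,
segmentation, back-projection, filtering, height extraction — can be tested
end to end without any field data.

Two degradation operators emulate the two real depth sources:

* :func:`degrade_to_arcore` — the coarse metric map: valid-aware Gaussian
  edge blur (sparse-to-dense reconstruction smears object boundaries),
  millimeter quantization, clamping to the 16-bit sensor range, and random
  pixel dropout (holes).
* :func:`make_relative` — the fine unitless map: the inverse affine transform
  R = (A - D)/S of the sharp truth plus Gaussian noise, edges preserved.

Default dimensions follow the validated capture envelope: shooting distances
2-17 m and tree heights 3.7-24.4 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import io as theio
from .types import DEPTH_MM_MAX, CameraIntrinsics, DepthMap, TreeMask

CAMERA_HEIGHT_M = 1.5  # phone held upright at chest height

# distance/height envelope of the validated capture protocol
DISTANCE_RANGE_M = (2.0, 17.0)
HEIGHT_RANGE_M = (3.7, 24.4)

_SKY = np.array([185, 205, 235], dtype=float)
_GROUND = np.array([115, 95, 60], dtype=float)
_TRUNK = np.array([95, 62, 35], dtype=float)
_CROWN = np.array([45, 112, 48], dtype=float)


@dataclass(frozen=True)
class TreeSpec:
    """One procedural tree: vertical trunk cylinder capped by a crown ellipsoid."""

    x_m: float                 # lateral offset of the axis, meters
    distance_m: float          # horizontal camera-to-axis distance, meters
    trunk_height_m: float
    trunk_radius_m: float
    crown_height_m: float
    crown_radius_m: float

    def __post_init__(self) -> None:
        for name in ("distance_m", "trunk_height_m", "trunk_radius_m",
                     "crown_height_m", "crown_radius_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def height_m(self) -> float:
        """Designed total height: trunk plus crown."""
        return self.trunk_height_m + self.crown_height_m


@dataclass
class SceneSpec:
    trees: List[TreeSpec]
    intrinsics: CameraIntrinsics
    camera_height_m: float = CAMERA_HEIGHT_M
    seed: int = 0


@dataclass(frozen=True)
class DegradationParams:
    """Knobs of the two emulated depth sources (see module docstring)."""

    edge_blur_sigma: float = 2.0        # pixels
    quantization_mm: float = 1.0
    clamp_mm: Tuple[float, float] = (0.0, DEPTH_MM_MAX)
    dropout_fraction: float = 0.02
    relative_scale: float = 80.0        # S_true, mm per relative unit
    relative_shift: float = 500.0       # D_true, mm
    # network prediction error = smooth low-frequency field + pixel noise;
    # depth-regression errors are spatially correlated, so the bulk of the
    # error budget sits in the smooth term (0.25 units = 20 mm RMS at the
    # default scale) with a small white component on top
    relative_noise_sigma: float = 0.05      # iid, relative units
    relative_smooth_sigma: float = 0.25     # field RMS, relative units
    relative_smooth_length_px: float = 48.0  # field correlation length

    def __post_init__(self) -> None:
        if self.edge_blur_sigma < 0:
            raise ValueError("blur sigma must be >= 0")
        if not (0 <= self.dropout_fraction < 1):
            raise ValueError("dropout fraction must be in [0, 1)")
        if self.relative_scale == 0:
            raise ValueError("relative scale must be nonzero")


def default_intrinsics(size: int = 512) -> CameraIntrinsics:
    """Wide-angle square pinhole camera scaled from the 512 px reference.

    The focal length (190 px at 512) and the principal point placed below
    the image center (cy = 365/512, i.e. the camera "aims up") are chosen so
    both ends of the validated envelope stay in frame with the camera 1.5 m
    above the ground: the crown top (including its near rim, which subtends
    the most) of the tallest trees, and the ground contact of a 3.7 m tree
    at 2 m.
    """
    s = size / 512.0
    return CameraIntrinsics(fx=190.0 * s, fy=190.0 * s,
                            cx=size / 2.0, cy=365.0 * s,
                            width=size, height=size)


# ---------------------------------------------------------------------------
# ray casting


def _ray_directions(K: CameraIntrinsics):
    u = np.arange(K.width, dtype=np.float64)
    v = np.arange(K.height, dtype=np.float64)
    uu, vv = np.meshgrid(u, v)
    dx = (uu - K.cx) / K.fx
    dy = (vv - K.cy) / K.fy
    return dx, dy  # dz = -1 everywhere; ray parameter t equals z-depth


def _intersect_plane(dy, cam_h):
    """t of the ray-ground intersection (plane y = cam_h, up = -y)."""
    t = np.full(dy.shape, np.inf)
    below = dy > 0
    t[below] = cam_h / dy[below]
    return t


def _intersect_cylinder(dx, dy, tree: TreeSpec, cam_h):
    """Vertical cylinder through (x0, z0), radius r, y in [cam_h - h, cam_h]."""
    x0, z0, r = tree.x_m, -tree.distance_m, tree.trunk_radius_m
    a = dx * dx + 1.0            # dz^2 = 1
    b = -2.0 * (dx * x0 - z0)    # dz*z0 = -z0
    c = x0 * x0 + z0 * z0 - r * r
    disc = b * b - 4 * a * c
    t = np.full(dx.shape, np.inf)
    hit = disc >= 0
    tt = (-b[hit] - np.sqrt(disc[hit])) / (2 * a[hit])
    y = tt * dy[hit]
    ok = (tt > 0) & (y <= cam_h) & (y >= cam_h - tree.trunk_height_m)
    vals = np.full(tt.shape, np.inf)
    vals[ok] = tt[ok]
    t[hit] = vals
    return t


CROWN_CUT_FRACTION = 0.65  # flat top at this fraction of the semi-height


def _intersect_ellipsoid(dx, dy, tree: TreeSpec, cam_h):
    """Flat-topped crown: ellipsoid truncated at 0.65 of its upper semi-axis.

    A full ellipsoid seen from below hides its own apex (the silhouette
    tangent sits below the pole), which no visible-surface measurement could
    recover; real crowns are irregular or umbrella-shaped, so the crown top
    is modeled as a flat cut whose rim sits exactly at the designed height.
    The bottom pole rests on the trunk top; semi-height b satisfies
    crown_height = b * (1 + cut).
    """
    cr = tree.crown_radius_m
    b_semi = tree.crown_height_m / (1.0 + CROWN_CUT_FRACTION)
    x0 = tree.x_m
    y_bottom = cam_h - tree.trunk_height_m      # bottom pole (junction)
    y0 = y_bottom - b_semi                       # center
    y_cut = y0 - CROWN_CUT_FRACTION * b_semi     # flat top (up = -y)
    z0 = -tree.distance_m
    ex, ey, ez = dx / cr, dy / b_semi, -1.0 / cr
    mx, my, mz = x0 / cr, y0 / b_semi, z0 / cr
    a = ex * ex + ey * ey + ez * ez
    b = -2.0 * (ex * mx + ey * my + ez * mz)
    c = mx * mx + my * my + mz * mz - 1.0
    disc = b * b - 4 * a * c
    t = np.full(dx.shape, np.inf)
    hit = disc >= 0
    tt = (-b[hit] - np.sqrt(disc[hit])) / (2 * a[hit])
    y = tt * dy[hit]
    ok = (tt > 0) & (y >= y_cut)   # hits above the cut plane are removed
    vals = np.full(tt.shape, np.inf)
    vals[ok] = tt[ok]
    t[hit] = vals
    return t


def render_scene(spec: SceneSpec):
    """Ray-cast the scene to (rgb, ground-truth DepthMap, TreeMask, heights).

    Depth is the per-pixel z-depth in float millimeters; pixels that hit
    nothing within the sensor range are invalid (value 0).  The mask labels
    the nearest-hit tree (trunk or crown) per pixel, 1..n in list order.
    True height of tree k is its designed trunk + crown extent.

    Raises
    ------
    ValueError
        If any tree produces no pixels (fully outside the frustum or hidden).
    """
    K = spec.intrinsics
    dx, dy = _ray_directions(K)
    cam_h = spec.camera_height_m

    t_best = _intersect_plane(dy, cam_h)
    surf = np.zeros(t_best.shape, dtype=np.int32)   # 0 ground, 2k-1 trunk, 2k crown
    for k, tree in enumerate(spec.trees, start=1):
        for t_prim, code in ((_intersect_cylinder(dx, dy, tree, cam_h), 2 * k - 1),
                             (_intersect_ellipsoid(dx, dy, tree, cam_h), 2 * k)):
            closer = t_prim < t_best
            t_best = np.where(closer, t_prim, t_best)
            surf = np.where(closer, code, surf)

    depth_mm = t_best * 1000.0
    valid = np.isfinite(depth_mm) & (depth_mm > 0) & (depth_mm <= DEPTH_MM_MAX)
    depth_mm = np.where(valid, depth_mm, 0.0)

    labels = np.where(valid & (surf > 0), (surf + 1) // 2, 0).astype(np.int32)
    mask = TreeMask(labels=labels)

    heights = [t.height_m for t in spec.trees]
    missing = [k for k in range(1, len(spec.trees) + 1) if not np.any(labels == k)]
    if missing:
        raise ValueError(f"trees {missing} are not visible in the frame "
                         "(outside the frustum or fully occluded)")

    rgb = np.empty(t_best.shape + (3,), dtype=float)
    rgb[~valid] = _SKY
    rgb[valid & (surf == 0)] = _GROUND
    rgb[valid & (surf % 2 == 1)] = _TRUNK
    rgb[valid & (surf > 0) & (surf % 2 == 0)] = _CROWN
    rng = np.random.default_rng(spec.seed)
    rgb = rgb + rng.normal(0.0, 8.0, size=rgb.shape)   # texture noise
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    return rgb, DepthMap(values=depth_mm, kind="absolute"), mask, heights


# ---------------------------------------------------------------------------
# degradation operators


def degrade_to_arcore(truth: DepthMap, params: DegradationParams = DegradationParams(),
                      seed: int = 0) -> DepthMap:
    """Coarse metric map: edge blur + mm quantization + clamping + dropout."""
    if truth.kind != "absolute":
        raise ValueError("degradation applies to absolute ground-truth depth")
    values = np.asarray(truth.values, dtype=float)
    valid = truth.valid.copy()
    if params.edge_blur_sigma > 0:
        num = gaussian_filter(np.where(valid, values, 0.0), params.edge_blur_sigma)
        den = gaussian_filter(valid.astype(float), params.edge_blur_sigma)
        blurred = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
        values = np.where(valid, blurred, 0.0)
    if params.quantization_mm > 0:
        values = np.rint(values / params.quantization_mm) * params.quantization_mm
    lo, hi = params.clamp_mm
    values = np.clip(values, lo, hi)
    if params.dropout_fraction > 0:
        rng = np.random.default_rng(seed)
        drop = rng.random(values.shape) < params.dropout_fraction
        valid = valid & ~drop
    values = np.where(valid, values, 0.0)
    return DepthMap(values=values, kind="absolute", valid=valid)


def make_relative(truth: DepthMap, params: DegradationParams = DegradationParams(),
                  seed: int = 0) -> DepthMap:
    """Fine unitless map: R = (A - D_true)/S_true + prediction error.

    Edges stay sharp.  The error has two parts: a smooth low-frequency field
    (depth networks err coherently over image regions, not per pixel) and a
    small iid component.  The map is dense (valid everywhere, like a network
    prediction); pixels with no ground truth are filled with the largest
    valid R value.
    """
    a = np.asarray(truth.values, dtype=float)
    r = (a - params.relative_shift) / params.relative_scale
    if truth.valid.any() and not truth.valid.all():
        r = np.where(truth.valid, r, r[truth.valid].max())
    rng = np.random.default_rng(seed)
    if params.relative_smooth_sigma > 0:
        field = gaussian_filter(rng.normal(size=r.shape),
                                params.relative_smooth_length_px)
        std = field.std()
        if std > 0:
            r = r + field * (params.relative_smooth_sigma / std)
    if params.relative_noise_sigma > 0:
        r = r + rng.normal(0.0, params.relative_noise_sigma, size=r.shape)
    return DepthMap(values=r.astype(np.float64), kind="relative")


# ---------------------------------------------------------------------------
# suite generation


def make_tree(height_m: float, distance_m: float, x_m: float = 0.0) -> TreeSpec:
    """Proportioned tree of a given total height: 35% trunk, 65% crown."""
    trunk_h = 0.35 * height_m
    crown_h = height_m - trunk_h
    return TreeSpec(x_m=x_m, distance_m=distance_m,
                    trunk_height_m=trunk_h,
                    trunk_radius_m=max(0.05, 0.013 * height_m),
                    crown_height_m=crown_h,
                    crown_radius_m=0.18 * height_m)


def suite_scene_specs(n_scenes: int, seed: int, size: int = 512) -> List[SceneSpec]:
    """Scene specs spanning the validated distance/height envelope.

    Distances step linearly over 2-17 m; tree height tracks distance at
    roughly 1.44x (as in typical single-tree captures where the tree fills
    the frame) with seeded jitter, clipped to 3.7-24.4 m.
    """
    if n_scenes < 1:
        raise ValueError("need at least one scene")
    rng = np.random.default_rng(seed)
    K = default_intrinsics(size)
    dists = np.linspace(*DISTANCE_RANGE_M, n_scenes)
    specs = []
    for i, dist in enumerate(dists):
        h = float(np.clip(1.44 * dist * rng.uniform(0.92, 1.08), *HEIGHT_RANGE_M))
        x = float(rng.uniform(-0.05, 0.05) * dist)
        specs.append(SceneSpec(trees=[make_tree(h, float(dist), x)],
                               intrinsics=K,
                               seed=int(rng.integers(0, 2 ** 31 - 1))))
    return specs


def generate_suite(n_scenes: int, seed: int, out_dir,
                   size: int = 512,
                   degradation: Optional[DegradationParams] = DegradationParams()):
    """Write ``n_scenes`` capture bundles plus a truth table to ``out_dir``.

    Each bundle holds the color image, the degraded absolute depth (16-bit
    PNG), the noisy relative depth (float TIFF), the intrinsics and the
    ground-truth instance mask.  ``truth.csv`` lists (scene, tree id, true
    height, shooting distance).  Passing ``degradation=None`` writes the
    exact ground-truth depth instead and no relative map.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(suite_scene_specs(n_scenes, seed, size)):
        rgb, truth, mask, heights = render_scene(spec)
        if degradation is not None:
            absolute = degrade_to_arcore(truth, degradation, seed=spec.seed + 1)
            relative = make_relative(truth, degradation, seed=spec.seed + 2)
        else:
            absolute, relative = truth, None
        bundle_dir = out_dir / f"scene_{i:03d}"
        theio.save_bundle(bundle_dir, rgb, absolute, spec.intrinsics,
                          relative=relative, mask=mask)
        for k, (tree, h) in enumerate(zip(spec.trees, heights), start=1):
            rows.append({"scene": f"scene_{i:03d}", "tree_id": k,
                         "true_height_m": h,
                         "shooting_distance_m": tree.distance_m})
    truth_df = pd.DataFrame(rows)
    truth_df.to_csv(out_dir / "truth.csv", index=False)
    return truth_df
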