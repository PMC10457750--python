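"""Tree morphometry from point clouds: axis-aligned boxes, heights, errors.

Tree height is the Y-extent of the axis-aligned bounding box of the denoised
per-tree cloud, in meters.  Accuracy against reference heights is summarized
as relative error percentages.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import AxisAlignedBox, PointCloud, TreeMeasurement


def bounding_box(cloud: PointCloud) -> AxisAlignedBox:
    """Componentwise min/max box of a non-empty cloud."""
    if len(cloud) == 0:
        raise ValueError("cannot box an empty cloud")
    mins = cloud.points.min(axis=0)
    maxs = cloud.points.max(axis=0)
    return AxisAlignedBox(min_corner=tuple(map(float, mins)),
                          max_corner=tuple(map(float, maxs)))


def tree_height(box: AxisAlignedBox, trim_percentile: float = 0.0,
                cloud: Optional[PointCloud] = None) -> float:
    """Tree height = Y-extent of the box, meters.

    ``trim_percentile`` > 0 (with the cloud supplied) measures the Y-extent
    between the p-th and (100-p)-th percentile instead, so a single
    surviving noise point cannot set the height; default off.
    """
    if trim_percentile < 0 or trim_percentile >= 50:
        raise ValueError("trim percentile must be in [0, 50)")
    if trim_percentile > 0:
        if cloud is None:
            raise ValueError("percentile trimming needs the point cloud")
        y = cloud.points[:, 1]
        lo, hi = np.percentile(y, [trim_percentile, 100.0 - trim_percentile])
        return float(hi - lo)
    return float(box.max_corner[1] - box.min_corner[1])


def relative_error(true_h: float, measured_h: float) -> float:
    """Unsigned relative error, percent: 100 * |measured - true| / true."""
    if true_h <= 0:
        raise ValueError("true height must be positive")
    return float(100.0 * abs(measured_h - true_h) / true_h)


def measure_tree(cloud: PointCloud, tree_id: int,
                 true_height_m: Optional[float] = None,
                 shooting_distance_m: Optional[float] = None,
                 trim_percentile: float = 0.0) -> TreeMeasurement:
    """Box a denoised tree cloud and report its height (and error if truth given)."""
    box = bounding_box(cloud)
    h = tree_height(box, trim_percentile=trim_percentile, cloud=cloud)
    return TreeMeasurement(tree_id=tree_id, height_m=h, n_points=len(cloud),
                           true_height_m=true_height_m,
                           shooting_distance_m=shooting_distance_m)


def measurements_table(measurements: Sequence[TreeMeasurement]) -> pd.DataFrame:
    """Per-tree table: true / measured height, shooting distance, relative error."""
    rows = []
    for m in measurements:
        rows.append({
            "tree_id": m.tree_id,
            "true_height_m": m.true_height_m,
            "measured_height_m": round(m.height_m, 2),
            "shooting_distance_m": None if m.shooting_distance_m is None
                                   else round(m.shooting_distance_m, 2),
            "relative_error_pct": None if m.relative_error_pct is None
                                  else round(m.relative_error_pct, 2),
            "n_points": m.n_points,
        })
    return pd.DataFrame(rows)


def evaluation_report(measurements: Sequence[TreeMeasurement]) -> dict:
    """Summary statistics over measurements that carry ground truth.

    Returns min / max / mean relative error (percent, unrounded), the
    measured-height range and the shooting-distance range, plus the per-tree
    table under ``"table"``.
    """
    with_truth = [m for m in measurements if m.true_height_m is not None]
    if not with_truth:
        raise ValueError("no measurements carry a true height")
    errs = np.array([m.relative_error_pct for m in with_truth], dtype=float)
    heights = np.array([m.height_m for m in with_truth], dtype=float)
    dists = [m.shooting_distance_m for m in with_truth
             if m.shooting_distance_m is not None]
    report = {
        "n_trees": len(with_truth),
        "min_relative_error_pct": float(errs.min()),
        "max_relative_error_pct": float(errs.max()),
        "mean_relative_error_pct": float(errs.mean()),
        "measured_height_range_m": (float(heights.min()), float(heights.max())),
        "table": measurements_table(with_truth),
    }
    if dists:
        report["shooting_distance_range_m"] = (float(min(dists)), float(max(dists)))
    return report
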