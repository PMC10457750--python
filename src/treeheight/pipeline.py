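"""End-to-end driver: align -> segment -> back-project -> split -> filter -> measure."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import io as theio
from .alignment import AffineDepthAlignment, apply_alignment, fit_scale_shift
from .measurement import measure_tree, measurements_table
from .reconstruction import RadiusFilterParams, backproject, radius_filter, split_by_label
from .seg import extract_instances, predict_mask
from .types import CaptureBundle, DepthMap, PointCloud, TreeMask, TreeMeasurement

log = logging.getLogger("treeheight")


@dataclass
class PipelineConfig:
    """Defaults follow the published measurement protocol: depth scale 1000
    mm/m, radius filter 1.5 m with a 10-neighbor count."""

    scale: float = 1000.0
    radius_filter: RadiusFilterParams = field(default_factory=RadiusFilterParams)
    min_instance_area: int = 50
    robust_alignment: bool = False
    trim_percentile: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class PipelineResult:
    measurements: List[TreeMeasurement]
    unmeasurable: List[int]
    alignment: Optional[AffineDepthAlignment]
    aligned_depth: DepthMap
    mask: TreeMask
    scene_cloud: PointCloud
    tree_clouds: Dict[int, PointCloud]


def _stage(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed_ms=%.1f %s", name, (time.perf_counter() - t0) * 1e3, extras)


def run_pipeline(bundle: CaptureBundle, config: PipelineConfig = None,
                 mask: Optional[TreeMask] = None, net=None) -> PipelineResult:
    """Measure every tree in a capture bundle.

    The mask comes either from a trained network (``net``) or from an
    externally supplied ``mask`` (e.g. ground truth, decoupling geometry
    from segmentation).  If the bundle carries a relative depth map it is
    affine-aligned to the absolute map and used for reconstruction
    (edge-sharp metric depth); otherwise the absolute map is used directly.
    Trees whose filtered cloud is empty are reported in ``unmeasurable``.
    """
    config = config or PipelineConfig()

    t0 = time.perf_counter()
    alignment = None
    if bundle.relative_depth is not None:
        alignment = fit_scale_shift(bundle.relative_depth, bundle.absolute_depth,
                                    robust=config.robust_alignment)
        aligned = apply_alignment(bundle.relative_depth, alignment)
        _stage("align", t0, S=f"{alignment.S:.4f}", D=f"{alignment.D:.1f}",
               n=alignment.n_pixels, rms_mm=f"{alignment.residual_rms:.1f}")
    else:
        aligned = bundle.absolute_depth
        _stage("align", t0, skipped="no relative depth")

    t0 = time.perf_counter()
    if mask is None:
        if net is None:
            raise ValueError("a mask or a trained segmentation network is required")
        semantic = predict_mask(net, bundle.rgb, aligned)
        mask = extract_instances(semantic, min_area=config.min_instance_area)
        _stage("segment", t0, instances=mask.n_instances)
    else:
        _stage("segment", t0, supplied=True, instances=mask.n_instances)
    if mask.n_instances == 0:
        log.warning("mask contains no trees; nothing to measure")

    t0 = time.perf_counter()
    scene = backproject(aligned, rgb=bundle.rgb, mask=mask,
                        K=bundle.intrinsics, scale=config.scale)
    _stage("reconstruct", t0, points=len(scene))

    t0 = time.perf_counter()
    per_tree = split_by_label(scene)
    _stage("split", t0, trees=len(per_tree))

    measurements, unmeasurable, clouds = [], [], {}
    for tree_id, cloud in sorted(per_tree.items()):
        t0 = time.perf_counter()
        filtered = radius_filter(cloud, config.radius_filter)
        _stage("denoise", t0, tree=tree_id, kept=len(filtered), of=len(cloud))
        if len(filtered) == 0:
            log.warning("tree %d: all %d points removed by radius filter; "
                        "unmeasurable", tree_id, len(cloud))
            unmeasurable.append(tree_id)
            continue
        clouds[tree_id] = filtered
        measurements.append(measure_tree(filtered, tree_id,
                                         trim_percentile=config.trim_percentile))
    return PipelineResult(measurements=measurements, unmeasurable=unmeasurable,
                          alignment=alignment, aligned_depth=aligned, mask=mask,
                          scene_cloud=scene, tree_clouds=clouds)


def save_results(result: PipelineResult, out_dir) -> Path:
    """Write all stage intermediates and the measurement table to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    theio.write_depth_png(result.aligned_depth, out / "aligned_depth.png")
    theio.write_mask_png(result.mask, out / "mask.png")
    if len(result.scene_cloud):
        theio.write_point_cloud(result.scene_cloud, out / "scene.ply")
    for k, cloud in result.tree_clouds.items():
        theio.write_point_cloud(cloud, out / f"tree_{k}.ply")
    measurements_table(result.measurements).to_csv(out / "measurements.csv", index=False)
    summary = {
        "n_trees": len(result.measurements),
        "heights_m": {m.tree_id: round(m.height_m, 2) for m in result.measurements},
        "unmeasurable": result.unmeasurable,
    }
    if result.alignment is not None:
        summary["alignment"] = {"S": result.alignment.S, "D": result.alignment.D,
                                "n_pixels": result.alignment.n_pixels,
                                "residual_rms_mm": result.alignment.residual_rms}
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return out
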