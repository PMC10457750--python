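"""Segmentation quality metrics and instance extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from ..types import TreeMask


@dataclass(frozen=True)
class SegMetrics:
    iou: float              # intersection-over-union of the tree class, percent
    pixel_accuracy: float   # fraction of correctly classified pixels, percent

    def __post_init__(self) -> None:
        if not (0 <= self.iou <= 100 and 0 <= self.pixel_accuracy <= 100):
            raise ValueError("metrics must lie in [0, 100]")


def seg_metrics(pred, truth) -> SegMetrics:
    """IoU and pixel accuracy of a binary prediction against a binary truth.

    Accepts TreeMasks or boolean/integer rasters; nonzero = tree.  An empty
    union (both masks empty) defines IoU = 100.
    """
    p = (pred.labels if isinstance(pred, TreeMask) else np.asarray(pred)) > 0
    t = (truth.labels if isinstance(truth, TreeMask) else np.asarray(truth)) > 0
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    union = np.logical_or(p, t).sum()
    inter = np.logical_and(p, t).sum()
    iou = 100.0 if union == 0 else 100.0 * inter / union
    pa = 100.0 * (p == t).mean()
    return SegMetrics(iou=float(iou), pixel_accuracy=float(pa))


def extract_instances(binary_mask, min_area: int = 0) -> TreeMask:
    """Label 4-connected components 1..k in decreasing area order.

    Components smaller than ``min_area`` pixels are dropped.  The semantic
    network head predicts tree vs background; individual trees are recovered
    here as connected components.
    """
    b = (binary_mask.labels if isinstance(binary_mask, TreeMask)
         else np.asarray(binary_mask)) > 0
    comps = cc_label(b, connectivity=1)
    out = np.zeros(b.shape, dtype=np.int64)
    ids, areas = np.unique(comps[comps > 0], return_counts=True)
    order = ids[np.argsort(-areas, kind="stable")]
    next_label = 1
    for cid in order:
        area = areas[ids == cid][0]
        if area < min_area:
            continue
        out[comps == cid] = next_label
        next_label += 1
    return TreeMask(labels=out)
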