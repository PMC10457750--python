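"""Training loop, input normalization and spatial augmentation."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from ..types import DepthMap, TreeMask
from . import nn
from .network import SegNetConfig, DepthAttentionUNet


def normalize_depth(depth: DepthMap) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] over valid pixels.

    Invalid pixels map to 0.  Works for absolute and relative maps alike
    (the network only needs relative ordering within the image).
    """
    values = np.asarray(depth.values, dtype=np.float64)
    valid = depth.valid
    out = np.zeros_like(values)
    if valid.any():
        v = values[valid]
        lo, hi = v.min(), v.max()
        if hi > lo:
            out[valid] = (values[valid] - lo) / (hi - lo)
        else:
            out[valid] = 0.5
    return out


def _to_batch(samples: Sequence[tuple]) -> tuple:
    """(rgb uint8, DepthMap, TreeMask) triples -> NCHW arrays + target."""
    rgbs, depths, targets = [], [], []
    for rgb, depth, mask in samples:
        rgbs.append(np.asarray(rgb, dtype=np.float64).transpose(2, 0, 1) / 255.0)
        depths.append(normalize_depth(depth)[None])
        targets.append((np.asarray(mask.labels) > 0).astype(np.float64)[None])
    return np.stack(rgbs), np.stack(depths), np.stack(targets)


def augment(rgb: np.ndarray, depth: DepthMap, mask: TreeMask, seed: int,
            crop_fraction: float = 0.8,
            scale_range: Tuple[float, float] = (0.9, 1.1),
            force_flip: Optional[bool] = None) -> tuple:
    """One random spatial augmentation applied identically to all rasters.

    Horizontal flip (p = 0.5), uniform scale jitter, then a random crop of
    ``crop_fraction`` of the frame resized back to the original size.  The
    mask and the depth raster are resampled nearest-neighbor, so labels stay
    integral and metric depth values are never blended or rescaled.
    """
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    rgb_a = np.asarray(rgb, dtype=np.float64)
    dep_a = np.asarray(depth.values, dtype=np.float64)
    val_a = depth.valid.astype(np.float64)
    lab_a = np.asarray(mask.labels, dtype=np.float64)

    flip = rng.random() < 0.5 if force_flip is None else force_flip
    if flip:
        rgb_a, dep_a, val_a, lab_a = (np.flip(a, axis=1) for a in
                                      (rgb_a, dep_a, val_a, lab_a))

    def _resize(arr, shape, order):
        return resize(arr, shape, order=order, preserve_range=True,
                      anti_aliasing=False)

    s = rng.uniform(*scale_range)
    if s != 1.0:
        hs, ws = max(8, round(h * s)), max(8, round(w * s))
        rgb_a = _resize(rgb_a, (hs, ws) + rgb_a.shape[2:], 1)
        dep_a = _resize(dep_a, (hs, ws), 0)
        val_a = _resize(val_a, (hs, ws), 0)
        lab_a = _resize(lab_a, (hs, ws), 0)

    ch, cw = max(4, round(h * crop_fraction)), max(4, round(w * crop_fraction))
    ch, cw = min(ch, lab_a.shape[0]), min(cw, lab_a.shape[1])
    top = rng.integers(0, lab_a.shape[0] - ch + 1)
    left = rng.integers(0, lab_a.shape[1] - cw + 1)
    crops = [a[top:top + ch, left:left + cw] for a in (rgb_a, dep_a, val_a, lab_a)]
    rgb_a = _resize(crops[0], (h, w) + rgb_a.shape[2:], 1)
    dep_a, val_a, lab_a = (_resize(a, (h, w), 0) for a in crops[1:])

    depth_out = DepthMap(values=dep_a, kind=depth.kind, valid=val_a > 0.5)
    return (np.clip(rgb_a, 0, 255).astype(np.uint8), depth_out,
            TreeMask(labels=np.rint(lab_a).astype(np.int64)))


def train(dataset: Sequence[tuple], config: SegNetConfig, seed: int = 0,
          net: Optional[DepthAttentionUNet] = None,
          use_augment: bool = False) -> tuple:
    """Optimize a (new or given) network on (rgb, depth, mask) triples.

    Runs ``config.total_steps`` Adam steps at ``config.learning_rate`` on
    batches of ``config.batch_size`` samples drawn with a seeded generator;
    returns ``(network, per-step loss list)``.  Fully deterministic given the
    seed.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    shapes = {tuple(np.asarray(m.labels).shape) for _, _, m in dataset}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent raster sizes in dataset: {shapes}")
    if net is None:
        net = DepthAttentionUNet(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    losses: List[float] = []
    for step in range(config.total_steps):
        idx = rng.integers(0, len(dataset), size=min(config.batch_size, len(dataset)))
        batch = [dataset[i] for i in idx]
        if use_augment:
            batch = [augment(r, d, m, seed=int(rng.integers(2 ** 31)))
                     for r, d, m in batch]
        rgb, depth, target = _to_batch(batch)
        logits = net.forward(rgb, depth)
        loss = nn.bce_with_logits(logits, target)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return net, losses


def predict_mask(net, rgb: np.ndarray, depth: DepthMap,
                 threshold: float = 0.5) -> TreeMask:
    """Binary tree/background prediction for one image."""
    batch_rgb, batch_depth, _ = _to_batch([(rgb, depth, TreeMask(
        labels=np.zeros(np.asarray(rgb).shape[:2], dtype=np.int64)))])
    logits = net.forward(batch_rgb, batch_depth)
    prob = 1.0 / (1.0 + np.exp(-logits.data[0, 0]))
    return TreeMask(labels=(prob > threshold).astype(np.int64))
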