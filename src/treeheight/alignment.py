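"""Affine scale-and-shift alignment of relative to absolute depth.

A monocular depth network produces a fine-grained but unitless map R; a
depth-from-motion sensor produces a coarse metric map A (millimeters).  The
two are related by an affine transform

    A = S * R + D

whose scale S and displacement D are estimated by ordinary least squares over
the jointly valid pixels.  Applying the fitted transform to R yields an
edge-sharp map on the metric scale.  The module also provides the standard
monocular-depth quality metrics (half mean-squared-error loss and
delta-threshold accuracy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import DEPTH_MM_MAX, DepthMap


@dataclass(frozen=True)
class AffineDepthAlignment:
    """Fitted affine map: absolute = S * relative + D (millimeters)."""

    S: float
    D: float
    n_pixels: int
    residual_rms: float

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("alignment needs at least 2 pixels")
        if self.residual_rms < 0:
            raise ValueError("residual RMS cannot be negative")


@dataclass
class DepthPair:
    """Predicted vs. ground-truth depth sharing a validity mask."""

    predicted: DepthMap
    truth: DepthMap

    def __post_init__(self) -> None:
        if self.predicted.shape != self.truth.shape:
            raise ValueError("depth pair shapes differ")

    @property
    def joint_valid(self) -> np.ndarray:
        return self.predicted.valid & self.truth.valid

    @property
    def M(self) -> int:
        return int(self.joint_valid.sum())

    def flat(self) -> tuple:
        """Jointly valid (predicted, truth) values, raster order."""
        m = self.joint_valid
        return (np.asarray(self.predicted.values, dtype=float)[m],
                np.asarray(self.truth.values, dtype=float)[m])


def _joint_values(relative: DepthMap, absolute: DepthMap):
    if relative.shape != absolute.shape:
        raise ValueError("relative and absolute maps must share shape")
    m = relative.valid & absolute.valid
    r = np.asarray(relative.values, dtype=float)[m]
    a = np.asarray(absolute.values, dtype=float)[m]
    return r, a


def fit_scale_shift(relative: DepthMap, absolute: DepthMap,
                    robust: bool = False) -> AffineDepthAlignment:
    """Least-squares fit of (S, D) in A = S*R + D over jointly valid pixels.

    Uses the closed-form normal equations; the result is independent of pixel
    traversal order.  With ``robust=True`` a single trimmed refit is done
    after dropping residuals larger than 3x the initial RMS.

    Raises
    ------
    ValueError
        If fewer than 2 jointly valid pixels exist or R has zero variance
        (singular design).
    """
    r, a = _joint_values(relative, absolute)
    if r.size < 2:
        raise ValueError(f"need >= 2 jointly valid pixels, got {r.size}")
    S, D = _ols(r, a)
    if robust:
        resid = a - (S * r + D)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        if rms > 0:
            keep = np.abs(resid) <= 3.0 * rms
            if keep.sum() >= 2 and np.ptp(r[keep]) > 0:
                S, D = _ols(r[keep], a[keep])
    if S < 0:
        warnings.warn("fitted scale S is negative: the relative map likely uses "
                      "an inverted depth convention", stacklevel=2)
    resid = a - (S * r + D)
    return AffineDepthAlignment(S=float(S), D=float(D), n_pixels=int(r.size),
                                residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def _ols(r: np.ndarray, a: np.ndarray) -> tuple:
    r_mean = r.mean()
    var = np.mean((r - r_mean) ** 2)
    if var == 0:
        raise ValueError("relative depth is constant over valid pixels (singular fit)")
    S = np.mean((r - r_mean) * (a - a.mean())) / var
    D = a.mean() - S * r_mean
    return float(S), float(D)


def apply_alignment(relative: DepthMap, align: AffineDepthAlignment) -> DepthMap:
    """Map a relative depth raster onto the metric scale.

    Values become S*R + D millimeters, clamped to the sensor range
    [0, 65535]; validity is inherited from the relative map.
    """
    values = align.S * np.asarray(relative.values, dtype=float) + align.D
    values = np.clip(values, 0.0, DEPTH_MM_MAX)
    # a clamped-to-zero pixel would otherwise be silently re-flagged invalid;
    # keep it valid at the range floor by nudging to the smallest positive mm
    values = np.where(relative.valid & (values <= 0), np.nextafter(0.0, 1.0), values)
    return DepthMap(values=values, kind="absolute", valid=relative.valid.copy())


def column_profile(depth: DepthMap, u: int) -> np.ndarray:
    """Valid (row, depth) pairs down image column ``u``, for diagnostics.

    Returns an (n, 2) array of (v, depth) in increasing row order; empty if
    the column holds no valid pixel.
    """
    h, w = depth.shape
    if not (0 <= u < w):
        raise IndexError(f"column {u} out of range [0, {w})")
    col_valid = depth.valid[:, u]
    rows = np.nonzero(col_valid)[0]
    vals = np.asarray(depth.values, dtype=float)[rows, u]
    return np.stack([rows.astype(float), vals], axis=1) if rows.size else np.empty((0, 2))


def depth_mse_loss(pair: DepthPair) -> float:
    """Half mean-squared depth error: (1/2M) * sum (d_i - d*_i)^2.

    M counts the jointly valid pixels.
    """
    d, d_star = pair.flat()
    if d.size == 0:
        raise ValueError("no jointly valid pixels (M = 0)")
    return float(np.sum((d - d_star) ** 2) / (2.0 * d.size))


def threshold_accuracy(pair: DepthPair, threshold: float = 1.25) -> float:
    """Percentage of jointly valid pixels with max(d/d*, d*/d) < threshold.

    The standard delta-accuracy metric for monocular depth; depths must be
    strictly positive on the valid set.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    d, d_star = pair.flat()
    if d.size == 0:
        raise ValueError("no jointly valid pixels")
    if np.any(d <= 0) or np.any(d_star <= 0):
        raise ValueError("delta accuracy requires positive depths on valid pixels")
    ratio = np.maximum(d / d_star, d_star / d)
    return float(100.0 * np.mean(ratio < threshold))
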