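"""Histogram features, the adaptive threshold model, and area constraints.

The coarse segmentation threshold is predicted from two features of the
image's gray-level distribution (computed on the preprocessed contrast
field): the peak position ``Mp`` — the gray level where the smoothed
histogram attains its maximum — and the rate of rise ``beta`` — the steepest
slope of the histogram on its ascent toward that peak.  A dataset-level
constant ``beta_u`` (the maximum rate of rise observed over the dataset) and
an adjustment factor ``k`` complete the model:

    T = Mp + k * (Mp^2 / 255) * (beta^l / beta_u - 1),   l = 2.

``Mp`` is the reference position; the correction pulls ``T`` below the peak
when the image's rise rate is weak relative to the dataset maximum (flat,
low-contrast images need a more inclusive threshold) and above it when the
rise is strong.  The parse of the correction term is isolated in
:func:`estimate_threshold` so alternates can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "HistogramFeatures",
    "ThresholdParams",
    "AreaConstraint",
    "extract_features",
    "estimate_threshold",
    "coarse_segment",
    "apply_area_constraint",
    "calibrate",
]

#: Scale applied to the per-pixel-normalized histogram slope so that beta
#: values land in a convenient numeric range (counts per bin per 1000 pixels).
BETA_SCALE = 1000.0


@dataclass
class HistogramFeatures:
    """Per-image histogram features feeding the threshold model.

    beta
        Maximum forward difference of the smoothed histogram on the ascent
        to the peak, per 1000 pixels (>= 0).
    m_p
        Gray level (integer bin) of the smoothed-histogram maximum.
    histogram
        Raw integer-binned counts (sum equals the pixel count).
    smoothed
        Moving-average-smoothed counts used for the peak/slope estimates.
    """

    beta: float
    m_p: int
    histogram: np.ndarray
    smoothed: np.ndarray
    n_pixels: int


@dataclass
class ThresholdParams:
    """Dataset-level parameters of the threshold model."""

    k: float
    beta_u: float
    l: float = 2.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.beta_u <= 0:
            raise ValueError(f"beta_u must be positive, got {self.beta_u}")


@dataclass
class AreaConstraint:
    """Component-area floor and background-hole-fill ceiling, in pixels."""

    min_area: int = 64
    fill_holes_below: int = 64

    def __post_init__(self) -> None:
        if self.min_area < 0 or self.fill_holes_below < 0:
            raise ValueError("area-constraint sizes must be non-negative")


def _moving_average(counts: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return counts.astype(np.float64)
    kernel = np.ones(width, dtype=np.float64) / width
    return np.convolve(counts.astype(np.float64), kernel, mode="same")


def extract_features(contrast: np.ndarray, smooth_width: int = 5) -> HistogramFeatures:
    """Extract (beta, Mp) from the integer-binned histogram of a contrast field.

    The histogram is smoothed with a centered moving average of
    ``smooth_width`` bins (1 disables smoothing).  ``Mp`` is the bin of the
    global smoothed maximum, ties broken toward the lowest bin.  ``beta`` is
    the maximum forward difference of the smoothed histogram over the
    ascending segment from the first nonzero bin up to ``Mp``, normalized by
    the pixel count and scaled by 1000; a degenerate (single-bin or
    peak-at-origin) histogram yields ``beta = 0``.
    """
    contrast = np.asarray(contrast, dtype=np.float64)
    if contrast.size == 0:
        raise ValueError("cannot extract features from an empty image")
    if smooth_width < 1 or smooth_width % 2 == 0:
        raise ValueError(f"smooth_width must be a positive odd integer, got {smooth_width}")

    bins = np.rint(np.clip(contrast, 0.0, None)).astype(np.int64).ravel()
    histogram = np.bincount(bins)
    n_pixels = int(contrast.size)
    smoothed = _moving_average(histogram, smooth_width)

    m_p = int(np.argmax(smoothed))  # argmax returns the lowest index on ties
    nonzero = np.nonzero(smoothed > 0)[0]
    first = int(nonzero[0]) if nonzero.size else 0

    if m_p > first:
        diffs = np.diff(smoothed[first : m_p + 1])
        beta = float(max(diffs.max(), 0.0)) / n_pixels * BETA_SCALE
    else:
        beta = 0.0

    return HistogramFeatures(
        beta=beta, m_p=m_p, histogram=histogram, smoothed=smoothed, n_pixels=n_pixels
    )


def estimate_threshold(
    features: HistogramFeatures | None,
    params: ThresholdParams,
    *,
    m_p: float | None = None,
    beta: float | None = None,
    max_value: float | None = None,
) -> float:
    """Evaluate the adaptive threshold model.

    ``m_p``/``beta`` default to the values in ``features`` but can be pinned
    (e.g. to a dataset-level Mp).  When ``max_value`` is given the threshold
    is clamped to ``[0, max_value]`` before use.
    """
    if m_p is None:
        if features is None:
            raise ValueError("either features or an explicit m_p is required")
        m_p = float(features.m_p)
    if beta is None:
        if features is None:
            raise ValueError("either features or an explicit beta is required")
        beta = float(features.beta)
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")

    correction = params.k * (m_p**2 / 255.0) * (beta**params.l / params.beta_u - 1.0)
    t = m_p + correction
    if max_value is not None:
        t = float(np.clip(t, 0.0, max_value))
    return float(t)


def coarse_segment(contrast: np.ndarray, threshold: float) -> np.ndarray:
    """Binarize the contrast field: foreground where ``C >= T``."""
    contrast = np.asarray(contrast, dtype=np.float64)
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    return (contrast >= threshold).astype(np.uint8)


_STRUCTURE_4 = ndimage.generate_binary_structure(2, 1)


def apply_area_constraint(mask: np.ndarray, constraint: AreaConstraint) -> np.ndarray:
    """Remove small foreground components and fill small background holes.

    4-connected foreground components with area < ``min_area`` are removed;
    4-connected background components that do not touch the image border and
    have area < ``fill_holes_below`` are filled.  No other pixel changes.
    """
    fg = np.asarray(mask) > 0

    if constraint.min_area > 0:
        labels, n = ndimage.label(fg, structure=_STRUCTURE_4)
        if n:
            sizes = np.bincount(labels.ravel())
            small = sizes < constraint.min_area
            small[0] = False
            fg = fg & ~small[labels]

    if constraint.fill_holes_below > 0:
        labels, n = ndimage.label(~fg, structure=_STRUCTURE_4)
        if n:
            border = np.zeros(n + 1, dtype=bool)
            for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
                border[np.unique(edge)] = True
            sizes = np.bincount(labels.ravel(), minlength=n + 1)
            fillable = (~border) & (sizes < constraint.fill_holes_below)
            fillable[0] = False
            fg = fg | fillable[labels]

    return fg.astype(np.uint8)


def calibrate(images, truths, k_grid, config=None) -> ThresholdParams:
    """Fit (k, beta_u) from annotated image/mask pairs.

    ``beta_u`` is the maximum per-image rate of rise over the calibration set.
    ``k`` is chosen from ``k_grid`` by exhaustively running the full
    segmentation pipeline at each grid point and keeping the value that
    maximizes the mean pixel F1 over the pairs (ties broken toward the
    smallest k).  ``l`` stays fixed at 2.
    """
    from . import pipeline  # local import: calibration drives the full pipeline

    from .config import PipelineConfig
    from .metrics import compute_metrics, confusion_counts

    images = list(images)
    truths = [np.asarray(t) > 0 for t in truths]
    if not images or len(images) != len(truths):
        raise ValueError("calibration requires equally many images and truth masks")
    k_grid = sorted(float(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    config = config or PipelineConfig()

    for img, truth in zip(images, truths):
        shape = img.pixels.shape if hasattr(img, "pixels") else np.asarray(img).shape
        if shape != truth.shape:
            raise ValueError(f"image/truth dimension mismatch: {shape} vs {truth.shape}")

    betas = [
        pipeline.prepare_contrast(img, config).features.beta for img in images
    ]
    beta_u = max(betas)
    if beta_u <= 0:
        beta_u = 1.0  # degenerate calibration set: fall back to a unit scale

    best_k, best_f1 = k_grid[0], -1.0
    for k in k_grid:
        cfg = config.replace(k=k, beta_u=beta_u)
        f1s = []
        for img, truth in zip(images, truths):
            result = pipeline.segment_image(img, cfg)
            m = compute_metrics(confusion_counts(result.mask, truth))
            if m.f1 is not None:
                f1s.append(m.f1)
        mean_f1 = float(np.mean(f1s)) if f1s else 0.0
        if mean_f1 > best_f1 + 1e-12:
            best_k, best_f1 = k, mean_f1

    return ThresholdParams(k=best_k, beta_u=beta_u)
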