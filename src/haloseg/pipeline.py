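"""End-to-end segmentation pipeline.

Stage order for each image: grayscale input -> local-contrast preprocessing
-> percentile rescale onto a 0-255 working range -> histogram features
(beta, Mp) -> adaptive threshold -> coarse binarization -> area constraint
-> halo correction.  Every intermediate scalar is kept on the result object
so a run is fully auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import halo, imaging, threshold
from .config import PipelineConfig
from .imaging import GrayImage
from .threshold import HistogramFeatures, ThresholdParams

__all__ = ["SegmentationResult", "ContrastPrep", "prepare_contrast", "segment_image"]

logger = logging.getLogger("haloseg")


@dataclass
class ContrastPrep:
    """Preprocessed working field and its histogram features."""

    contrast: np.ndarray  # rescaled working field (or raw gray if no preprocess)
    raw_contrast: np.ndarray | None  # unscaled local-contrast field
    features: HistogramFeatures


@dataclass
class SegmentationResult:
    mask: np.ndarray
    coarse_mask: np.ndarray
    contrast: np.ndarray
    features: HistogramFeatures
    threshold: float
    halo_iterations: int
    halo_converged: bool
    confluency: float


def _gray_pixels(image) -> np.ndarray:
    if isinstance(image, GrayImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def prepare_contrast(image, config: PipelineConfig | None = None) -> ContrastPrep:
    """Compute the working field the threshold model operates on.

    With preprocessing on, this is the local-contrast field rescaled so its
    ``rescale_percentile`` maps to ``rescale_level`` (clipped above): the
    contrast field is unbounded and scales with exposure, so the rescale puts
    its integer-binned histogram on a stable, exposure-free range.  With
    preprocessing off, the raw gray image is used unchanged (ablation mode).
    """
    config = config or PipelineConfig()
    pixels = _gray_pixels(image)

    if config.preprocess:
        window = imaging.gaussian_window(config.window_side, config.sigma)
        raw = imaging.local_contrast(pixels, window)
        ref = float(np.percentile(raw, config.rescale_percentile))
        if ref <= 0:
            ref = float(raw.max()) or 1.0
        working = np.clip(raw / ref * config.rescale_level, 0.0, config.rescale_level)
    else:
        raw = None
        working = pixels

    features = threshold.extract_features(working, config.smooth_width)
    return ContrastPrep(contrast=working, raw_contrast=raw, features=features)


def segment_image(image, config: PipelineConfig | None = None) -> SegmentationResult:
    """Segment one grayscale image and return the mask with diagnostics."""
    config = config or PipelineConfig()
    pixels = _gray_pixels(image)

    prep = prepare_contrast(pixels, config)
    params = ThresholdParams(k=config.k, beta_u=config.beta_u, l=config.l)
    t = threshold.estimate_threshold(
        prep.features,
        params,
        m_p=config.fixed_m_p,
        max_value=float(prep.contrast.max()),
    )

    coarse = threshold.coarse_segment(prep.contrast, t)
    constrained = threshold.apply_area_constraint(
        coarse,
        threshold.AreaConstraint(
            min_area=config.min_area, fill_holes_below=config.fill_holes_below
        ),
    )

    operand = pixels if config.gradient_on == "gray" else prep.contrast
    if config.gradient_smooth_sigma > 0:
        operand = ndimage.gaussian_filter(operand, config.gradient_smooth_sigma)
    halo_cfg = halo.HaloCorrectionConfig(
        max_iterations=config.max_iterations,
        gradient_epsilon=config.gradient_epsilon,
        direction=config.direction,
    )
    result = halo.halo_correct_result(operand, constrained, halo_cfg)

    confluency = float(np.count_nonzero(result.mask) / result.mask.size)
    logger.info(
        "segmented image: beta=%.3f Mp=%d T=%.3f halo_iterations=%d confluency=%.4f",
        prep.features.beta,
        prep.features.m_p,
        t,
        result.iterations,
        confluency,
    )
    return SegmentationResult(
        mask=result.mask,
        coarse_mask=constrained,
        contrast=prep.contrast,
        features=prep.features,
        threshold=t,
        halo_iterations=result.iterations,
        halo_converged=result.converged,
        confluency=confluency,
    )
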