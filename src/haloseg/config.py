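"""Pipeline configuration and dataset parameter profiles.

Threshold-model parameters (``k``, ``beta_u`` and optionally a pinned
``Mp``) are dataset properties: they are fitted once per imaging setup by
:func:`haloseg.threshold.calibrate` and then reused for every image of that
dataset.  Profiles for the two benchmark stem-cell datasets (C2C12 murine
myoblasts and human mesenchymal stem cells) ship with the package, alongside
a ``phantom`` profile calibrated on the synthetic generator's default scenes
(see ``docs/methods.md`` for the calibration procedure).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "PROFILES", "load_config", "save_config"]

#: Published per-dataset parameters for the two benchmark datasets, plus the
#: parameters calibrated on the synthetic phantom defaults.  ``m_p`` is used
#: only when the per-image peak estimate is explicitly pinned (``fixed_m_p``).
PROFILES: dict[str, dict[str, float]] = {
    "c2c12": {"k": 0.86, "beta_u": 30.99, "m_p": 276.0},
    "hmscs": {"k": 1.68, "beta_u": 27.45, "m_p": 209.0},
    # fitted with threshold.calibrate on ten default phantom scenes spanning
    # confluency 0.1-0.5 (k grid 0.5..3.0 in steps of 0.5)
    "phantom": {"k": 2.5, "beta_u": 39.5081, "m_p": 3.0},
}


@dataclass
class PipelineConfig:
    """All knobs of the segmentation pipeline, with phantom-profile defaults.

    Threshold model: ``k`` (dimensionless adjustment), ``l`` (exponent, 2),
    ``beta_u`` (dataset maximum rate of rise), ``fixed_m_p`` (pin the
    histogram peak instead of estimating it per image).

    Preprocessing: ``window_side``/``sigma`` of the Gaussian contrast window,
    ``smooth_width`` of the histogram moving average, and the percentile used
    to rescale the unbounded contrast field onto a 0-255 working range.
    ``preprocess=False`` thresholds the raw gray image instead (ablation).

    Area constraint: ``min_area`` (component floor, px) and
    ``fill_holes_below`` (hole-fill ceiling, px).

    Halo correction: ``max_iterations`` safeguard, ``gradient_epsilon``
    (minimum gradient, in intensity units, to keep advancing — a margin of a
    few gray levels keeps sensor noise from driving the contour), a light
    Gaussian smoothing of the gradient operand (``gradient_smooth_sigma``,
    0 disables), ``direction`` ("shrink": the coarse contour sits at the
    halo's outer edge and is peeled inward up the ramp to the ridge; "grow":
    the contour starts inside and advances outward) and ``gradient_on``
    ("gray": the intensity image whose halo profile the stopping rule
    describes; "contrast": the preprocessed field).
    """

    k: float = PROFILES["phantom"]["k"]
    beta_u: float = PROFILES["phantom"]["beta_u"]
    l: float = 2.0
    fixed_m_p: float | None = None

    window_side: int = 3
    sigma: float = 0.8
    smooth_width: int = 5
    rescale_percentile: float = 99.5
    rescale_level: float = 255.0
    preprocess: bool = True

    min_area: int = 64
    fill_holes_below: int = 64

    max_iterations: int = 20
    gradient_epsilon: float = 5.0
    gradient_smooth_sigma: float = 1.5
    direction: str = "shrink"
    gradient_on: str = "gray"

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_profile(cls, name: str, *, pin_m_p: bool = False, **overrides) -> "PipelineConfig":
        """Build a config from a named dataset profile.

        ``pin_m_p=True`` fixes the histogram peak to the profile's published
        per-dataset value instead of estimating it per image.
        """
        if name not in PROFILES:
            raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
        prof = PROFILES[name]
        kwargs = {"k": prof["k"], "beta_u": prof["beta_u"]}
        if pin_m_p:
            kwargs["fixed_m_p"] = prof["m_p"]
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def save_config(config: PipelineConfig, path) -> None:
    """Write a config as YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config written by :func:`save_config`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return PipelineConfig.from_dict(data)
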