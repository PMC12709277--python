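"""Seeded synthetic phase-contrast phantoms with exact ground truth.

Each scene places randomly perturbed elliptical "cells" on a mid-gray
background and renders intensity from the signed distance ``s`` to the
nearest true cell boundary (``s < 0`` inside):

* deep interior (``s <= -ramp_inside``): a dark plateau at
  ``cell_intensity * background_level``, optionally modulated by smooth
  multiplicative texture emulating organelle-scale structure;
* across the boundary: intensity rises smoothly (cosine taper) from the cell
  plateau to a bright halo ridge ``halo_peak_gain * background_level`` at
  ``halo_width / 2`` outside the boundary;
* beyond the ridge: intensity decays back to the background level by
  ``halo_width`` outside.

This reproduces the characteristic rise-then-fall profile of phase-contrast
halos — the structure the halo-correction stopping rule relies on — with the
intensity maximum strictly outside the true boundary.  A planar illumination
tilt and Gaussian pixel noise are added last.  Identical seeds give
bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import GrayImage, write_image, write_mask

__all__ = ["PhantomConfig", "PhantomScene", "generate_scene", "generate_dataset"]

#: Random Fourier harmonics used for the radial boundary perturbation.
_HARMONICS = (2, 3, 4, 5)


@dataclass
class PhantomConfig:
    """Scene geometry, optics and noise settings for the phantom generator.

    Intensities are on an 8-bit scale.  ``cell_texture`` is the relative
    amplitude of the smooth multiplicative texture inside cell bodies and
    ``texture_scale`` its correlation length in pixels; real phase-contrast
    cell interiors are locally busy at roughly organelle scale, which is what
    makes them separable from the flat background in the local-contrast field.
    """

    height: int = 256
    width: int = 256
    n_cells: int = 8
    radius_range: tuple[float, float] = (12.0, 24.0)
    cell_intensity: float = 0.75
    background_level: float = 120.0
    halo_peak_gain: float = 1.5
    halo_width: float = 4.0
    ramp_inside: float = 2.0
    illumination_tilt: float = 0.1
    noise_sigma: float = 3.0
    shape_irregularity: float = 0.25
    cell_texture: float = 0.15
    texture_scale: float = 1.5
    seed: int = 0
    #: optional explicit (row, col, radius) triples; overrides random placement
    cells: list | None = None

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if 2 * rmax > min(self.height, self.width):
            raise ValueError(
                f"radius_range {self.radius_range} does not fit a "
                f"{self.height}x{self.width} image"
            )
        for name in ("cell_intensity", "background_level", "halo_peak_gain", "halo_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class PhantomScene:
    """A rendered phantom with its exact ground truth."""

    image: GrayImage
    truth: np.ndarray  # {0,1} mask
    true_confluency: float
    cell_records: list = field(default_factory=list)


def _cell_mask(config: PhantomConfig, rng: np.random.Generator, radius_scale: float):
    """Draw cell geometry and rasterize the union truth mask."""
    h, w = config.height, config.width
    truth = np.zeros((h, w), dtype=bool)
    records = []
    rmin, rmax = config.radius_range
    if config.cells is not None:
        placements = [tuple(map(float, cell)) for cell in config.cells]
    else:
        placements = None
    for i in range(len(placements) if placements is not None else config.n_cells):
        if placements is not None:
            cy, cx, r = placements[i]
            rng.uniform(0, 1, 3)  # keep the draw stream aligned with random placement
        else:
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            r = rng.uniform(rmin, rmax)
        coeffs = rng.standard_normal(len(_HARMONICS))
        phases = rng.uniform(0, 2 * np.pi, len(_HARMONICS))
        norm = np.abs(coeffs).sum()
        if norm > 0:
            coeffs = coeffs / norm  # bounds the perturbation to +-1
        r = r * radius_scale

        lo_r = max(0, int(np.floor(cy - 2 * r)))
        hi_r = min(h, int(np.ceil(cy + 2 * r)) + 1)
        lo_c = max(0, int(np.floor(cx - 2 * r)))
        hi_c = min(w, int(np.ceil(cx + 2 * r)) + 1)
        if lo_r >= hi_r or lo_c >= hi_c:
            records.append({"row": cy, "col": cx, "radius": r})
            continue
        yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dy = yy - cy
        dx = xx - cx
        dist = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        perturb = np.zeros_like(theta)
        for hharm, c, ph in zip(_HARMONICS, coeffs, phases):
            perturb += c * np.cos(hharm * theta + ph)
        boundary = r * (1.0 + config.shape_irregularity * perturb)
        truth[lo_r:hi_r, lo_c:hi_c] |= dist <= boundary
        records.append({"row": cy, "col": cx, "radius": r})
    return truth, records


def _signed_distance(truth: np.ndarray) -> np.ndarray:
    """Signed distance to the mask boundary: negative inside, positive outside."""
    if not truth.any():
        return np.full(truth.shape, np.inf)
    if truth.all():
        return np.full(truth.shape, -np.inf)
    d_in = ndimage.distance_transform_edt(truth)
    d_out = ndimage.distance_transform_edt(~truth)
    # boundary sits between pixel centers; split the half-pixel symmetrically
    return np.where(truth, -(d_in - 0.5), d_out - 0.5)


def _radial_profile(s: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Noiseless intensity as a function of signed boundary distance."""
    bg = config.background_level
    cell = config.cell_intensity * bg
    peak = config.halo_peak_gain * bg
    hw2 = config.halo_width / 2.0
    ramp = config.ramp_inside

    v = np.full(s.shape, bg, dtype=np.float64)
    v[s <= -ramp] = cell

    rise = (s > -ramp) & (s <= hw2)
    t = (s[rise] + ramp) / (ramp + hw2)
    v[rise] = cell + (peak - cell) * 0.5 * (1.0 - np.cos(np.pi * t))

    decay = (s > hw2) & (s <= config.halo_width)
    u = (s[decay] - hw2) / hw2
    v[decay] = bg + (peak - bg) * 0.5 * (1.0 + np.cos(np.pi * u))
    return v


def _generate(config: PhantomConfig, radius_scale: float = 1.0) -> PhantomScene:
    rng = np.random.default_rng(config.seed)
    truth, records = _cell_mask(config, rng, radius_scale)
    s = _signed_distance(truth)
    v = _radial_profile(s, config)

    # smooth multiplicative texture inside cell bodies
    tex_field = rng.standard_normal((config.height, config.width))
    if config.cell_texture > 0 and truth.any():
        tex = ndimage.gaussian_filter(tex_field, config.texture_scale)
        std = tex.std()
        if std > 0:
            tex = tex / std
        v = np.where(truth, v * (1.0 + config.cell_texture * tex), v)

    # planar illumination tilt along a random direction
    phi = rng.uniform(0, 2 * np.pi)
    if config.illumination_tilt > 0:
        yy, xx = np.mgrid[0 : config.height, 0 : config.width]
        proj = (yy - config.height / 2) * np.sin(phi) + (xx - config.width / 2) * np.cos(phi)
        span = max(np.abs(proj).max(), 1.0)
        v = v * (1.0 + config.illumination_tilt * 0.5 * proj / span)

    noise = rng.normal(0.0, 1.0, (config.height, config.width))
    if config.noise_sigma > 0:
        v = v + config.noise_sigma * noise

    pixels = np.clip(np.rint(v), 0, 255).astype(np.uint8)
    image = GrayImage(pixels=pixels.astype(np.float64), bit_depth=8)
    truth8 = truth.astype(np.uint8)
    return PhantomScene(
        image=image,
        truth=truth8,
        true_confluency=float(truth.mean()),
        cell_records=records,
    )


def generate_scene(config: PhantomConfig) -> PhantomScene:
    """Render one phantom scene from its config (deterministic in the seed)."""
    return _generate(config)


def _scale_for_target(config: PhantomConfig, target: float, tol: float = 0.03):
    """Bisect a radius scale factor until the true confluency hits the target."""
    rmin, rmax = config.radius_range
    max_scale = min(config.height, config.width) / (2.0 * rmax)
    lo, hi = 0.05, max_scale

    def conf(scale: float) -> float:
        return _generate(config, radius_scale=scale).true_confluency

    c_hi = conf(hi)
    if c_hi + tol < target:
        raise ValueError(
            f"confluency target {target} unreachable: max packing reaches {c_hi:.3f}"
        )
    c_lo = conf(lo)
    if c_lo - tol > target:
        raise ValueError(
            f"confluency target {target} unreachable: minimum coverage is {c_lo:.3f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = conf(mid)
        if abs(c - target) <= tol:
            return mid
        if c < target:
            lo = mid
        else:
            hi = mid
    raise ValueError(f"confluency target {target} not reached within tolerance {tol}")


def generate_dataset(
    config: PhantomConfig,
    n_images: int,
    out_dir,
    confluency_targets=None,
    tol: float = 0.03,
) -> pd.DataFrame:
    """Write a phantom dataset (images, truth masks, manifest CSV).

    Per-image seeds are derived from ``config.seed``.  When
    ``confluency_targets`` is given (a scalar or one fraction per image), cell
    radii are rescaled by bisection until each scene's true confluency is
    within ``tol`` of its target.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if confluency_targets is not None:
        targets = np.broadcast_to(np.asarray(confluency_targets, dtype=float), (n_images,))
    else:
        targets = None

    rows = []
    for i in range(n_images):
        cfg = replace(config, seed=int((config.seed + i) % 2**31))
        if targets is not None:
            scale = _scale_for_target(cfg, float(targets[i]), tol=tol)
            scene = _generate(cfg, radius_scale=scale)
        else:
            scale = 1.0
            scene = generate_scene(cfg)
        image_path = out_dir / f"phantom_{i:03d}.png"
        mask_path = out_dir / f"phantom_{i:03d}_truth.png"
        write_image(scene.image, image_path)
        write_mask(scene.truth, mask_path)
        rows.append(
            {
                "image": image_path.name,
                "truth": mask_path.name,
                "seed": cfg.seed,
                "n_cells": cfg.n_cells,
                "radius_scale": scale,
                "true_confluency": scene.true_confluency,
                "target_confluency": float(targets[i]) if targets is not None else None,
            }
        )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
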