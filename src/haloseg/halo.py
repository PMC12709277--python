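"""Halo-artifact contour correction by directional gradient traversal.

Phase-contrast optics surround each cell with a bright halo: moving from the
cell outward, intensity rises through the halo to a ridge just outside the
true cell boundary and then falls back to the background level.  The coarse
threshold contour therefore rarely sits on the true boundary.  Correction
walks the contour along that intensity profile: from every contour pixel,
gradients to the eight neighbors (top, bottom, left, right and the four
diagonals) are evaluated, the contour advances into neighbors with a
positive gradient (ascending the halo ramp), and a point freezes once all
its outward gradients are negative — i.e. at the halo ridge.  Iteration
stops when every point is frozen or a safeguard cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HaloCorrectionConfig",
    "HaloResult",
    "extract_contours",
    "directional_gradients",
    "halo_correct",
    "halo_correct_result",
]

#: The eight traversal directions: top, bottom, left, right, top-left,
#: bottom-left, top-right, bottom-right (row/col offsets).
DIRECTIONS = (
    (-1, 0),
    (1, 0),
    (0, -1),
    (0, 1),
    (-1, -1),
    (1, -1),
    (-1, 1),
    (1, 1),
)


@dataclass
class HaloCorrectionConfig:
    """Termination safeguards and growth options for halo correction."""

    max_iterations: int = 20
    gradient_epsilon: float = 0.0
    direction: str = "grow"

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.direction not in ("grow", "shrink"):
            raise ValueError(f"direction must be 'grow' or 'shrink', got {self.direction!r}")


@dataclass
class HaloResult:
    """Corrected mask plus the iteration diagnostics."""

    mask: np.ndarray
    iterations: int
    converged: bool  # True if growth stopped by the negative-gradient rule


def _boundary(fg: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one 4-neighbor background pixel.

    The image border counts as background, so foreground pixels on the edge
    of the array are always boundary pixels.
    """
    padded = np.pad(fg, 1, mode="constant", constant_values=False)
    has_bg = (
        ~padded[:-2, 1:-1] | ~padded[2:, 1:-1] | ~padded[1:-1, :-2] | ~padded[1:-1, 2:]
    )
    return fg & has_bg


def _boundary_of_holes(fg: np.ndarray) -> np.ndarray:
    """Foreground pixels whose only background contact is an enclosed hole."""
    structure = ndimage.generate_binary_structure(2, 1)
    labels, n = ndimage.label(~fg, structure=structure)
    if n == 0:
        return np.zeros_like(fg)
    outer = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        outer[np.unique(edge)] = True
    outer[0] = True
    hole = (~outer[labels]) & ~fg
    padded = np.pad(hole, 1, mode="constant", constant_values=False)
    touches_hole = (
        padded[:-2, 1:-1] | padded[2:, 1:-1] | padded[1:-1, :-2] | padded[1:-1, 2:]
    )
    padded_bg = np.pad(~fg & ~hole, 1, mode="constant", constant_values=True)
    touches_outer = (
        padded_bg[:-2, 1:-1] | padded_bg[2:, 1:-1] | padded_bg[1:-1, :-2] | padded_bg[1:-1, 2:]
    )
    return fg & touches_hole & ~touches_outer


def extract_contours(mask: np.ndarray) -> list[tuple[int, int]]:
    """Boundary pixel set of a mask: foreground pixels 4-adjacent to background."""
    fg = np.asarray(mask) > 0
    rows, cols = np.nonzero(_boundary(fg))
    return list(zip(rows.tolist(), cols.tolist()))


def directional_gradients(image: np.ndarray, point: tuple[int, int]) -> np.ndarray:
    """Intensity gradients from ``point`` to its eight neighbors.

    Returns the eight values ``image[point + d] - image[point]`` in the
    order of :data:`DIRECTIONS`; out-of-bounds neighbors yield ``-inf`` so
    growth always halts at the image border.
    """
    img = np.asarray(image, dtype=np.float64)
    r, c = point
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise ValueError(f"point {point} outside image of shape {img.shape}")
    out = np.full(8, -np.inf)
    for i, (dr, dc) in enumerate(DIRECTIONS):
        rr, cc = r + dr, c + dc
        if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
            out[i] = img[rr, cc] - img[r, c]
    return out


def _shift(a: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Shift so that ``out[r, c] = a[r - dr, c - dc]``, padding with ``fill``."""
    out = np.full_like(a, fill)
    src_r = slice(max(0, -dr), a.shape[0] - max(0, dr))
    src_c = slice(max(0, -dc), a.shape[1] - max(0, dc))
    dst_r = slice(max(0, dr), a.shape[0] - max(0, -dr))
    dst_c = slice(max(0, dc), a.shape[1] - max(0, -dc))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def halo_correct_result(
    image: np.ndarray, mask: np.ndarray, config: HaloCorrectionConfig | None = None
) -> HaloResult:
    """Run halo correction and return the mask with iteration diagnostics."""
    config = config or HaloCorrectionConfig()
    img = np.asarray(image, dtype=np.float64)
    fg = np.asarray(mask) > 0
    if img.shape != fg.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {fg.shape}")

    eps = config.gradient_epsilon
    if config.direction == "grow":
        fg = fg.copy()
        active = _boundary(fg)
        iterations = 0
        converged = True
        while iterations < config.max_iterations:
            grown = np.zeros_like(fg)
            for dr, dc in DIRECTIONS:
                # out[q] true if q's neighbor p = q - d is an active contour
                # point and the gradient from p to q is positive.
                from_active = _shift(active, dr, dc, False)
                from_img = _shift(img, dr, dc, np.inf)
                grown |= from_active & ~fg & (img - from_img > eps)
            if not grown.any():
                break
            fg |= grown
            active = grown
            iterations += 1
        else:
            converged = False
        return HaloResult(mask=fg.astype(np.uint8), iterations=iterations, converged=converged)

    # shrink: peel contour pixels while intensity still rises toward the
    # interior (the initial contour sits outside the halo ridge).  Points
    # whose inward gradients are all <= eps freeze permanently — the contour
    # has reached the ridge there — and only pixels newly exposed by a
    # peeled neighbor become active, mirroring the per-point freezing of the
    # grow branch.  Only the exterior contour is corrected: boundaries of
    # interior holes are not halo edges, and neither is the field-of-view
    # edge where a cell is clipped by the image border, so those pixels
    # never seed or join the peeling front.
    fg = fg.copy()
    interior = np.zeros_like(fg)
    interior[1:-1, 1:-1] = True
    active = _boundary(fg) & ~_boundary_of_holes(fg) & interior
    frozen = np.zeros_like(fg)
    iterations = 0
    converged = True
    structure_8 = np.ones((3, 3), dtype=bool)
    while iterations < config.max_iterations:
        peel = np.zeros_like(fg)
        for dr, dc in DIRECTIONS:
            nb_fg = _shift(fg, -dr, -dc, False)  # nb_fg[p] = fg[p + d]
            nb_img = _shift(img, -dr, -dc, -np.inf)
            peel |= active & nb_fg & (nb_img - img > eps)
        if not peel.any():
            break
        frozen |= active & ~peel
        fg &= ~peel
        exposed = ndimage.binary_dilation(peel, structure=structure_8)
        active = _boundary(fg) & exposed & ~frozen & interior
        iterations += 1
    else:
        converged = False
    return HaloResult(mask=fg.astype(np.uint8), iterations=iterations, converged=converged)


def halo_correct(
    image: np.ndarray, mask: np.ndarray, config: HaloCorrectionConfig | None = None
) -> np.ndarray:
    """Corrected binary mask (see :func:`halo_correct_result` for diagnostics)."""
    return halo_correct_result(image, mask, config).mask
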