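"""Image I/O, grayscale conversion and local-contrast preprocessing.

Phase-contrast images of unstained cells have low absolute contrast between
cell bodies and background, but cell regions are locally *busy*: organelle
texture and the bright halo ramp produce high local variance, while the
background is flat.  The preprocessing stage therefore maps the gray image
``I(x, y)`` to a local-contrast field

    C = (w * I^2 - (w * I)^2) / (w * I)

where ``w`` is a small normalized Gaussian window and ``*`` is 2-D
convolution: the Gaussian-weighted local variance divided by the
Gaussian-weighted local mean (an index-of-dispersion contrast).  ``C`` is
non-negative, scales linearly with the image intensity, and is large exactly
where cells and halo edges are.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "GrayImage",
    "read_image",
    "write_image",
    "write_mask",
    "gaussian_window",
    "local_contrast",
]

#: Stabilizer added to the local-mean denominator so that all-black regions
#: (variance 0, mean 0) yield contrast 0 instead of 0/0.
MEAN_EPSILON = 1e-6

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayImage:
    """A single-channel intensity image with bit-depth metadata.

    Parameters
    ----------
    pixels
        2-D float array of intensities, all values in ``[0, 2**bit_depth - 1]``.
    bit_depth
        8 or 16; the dynamic range the pixels were quantized to.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={self.pixels.ndim}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError(f"image must be at least 3x3, got {self.pixels.shape}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _as_array(image) -> np.ndarray:
    if isinstance(image, GrayImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def read_image(path) -> GrayImage:
    """Read a single-channel or RGB TIFF/PNG into a :class:`GrayImage`.

    RGB inputs are converted to luminance grayscale; already-gray inputs are
    passed through unchanged.  The bit depth is inferred from the file dtype.
    Multi-frame stacks are rejected.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise OSError(f"could not read image file {path}: {exc}") from exc

    if arr.dtype == np.uint16:
        bit_depth = 16
    elif arr.dtype == np.uint8 or arr.dtype == bool:
        bit_depth = 8
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype} in {path}")

    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            rgb = arr[..., :3].astype(np.float64)
            arr = rgb @ LUMA_WEIGHTS
        else:
            raise ValueError(f"multi-frame stacks are not supported: {path}")
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")

    return GrayImage(pixels=np.asarray(arr, dtype=np.float64), bit_depth=bit_depth)


def write_image(image: GrayImage, path) -> None:
    """Write a :class:`GrayImage` at its native bit depth (8- or 16-bit)."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    out = np.clip(np.rint(image.pixels), 0, 2**image.bit_depth - 1).astype(dtype)
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not write image file {path}: {exc}") from exc


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit image with foreground 255, background 0."""
    path = Path(path)
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    try:
        iio.imwrite(path, out)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not write mask file {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a mask image into a {0,1} uint8 array (any positive pixel is 1)."""
    return (read_image(path).pixels > 0).astype(np.uint8)


def gaussian_window(side: int = 3, sigma: float = 0.8) -> np.ndarray:
    """Sampled isotropic Gaussian window, renormalized to sum exactly 1.

    Parameters
    ----------
    side
        Odd window side length in pixels, >= 3.
    sigma
        Gaussian standard deviation in pixels, > 0.
    """
    if side < 3 or side % 2 == 0:
        raise ValueError(f"window side must be an odd integer >= 3, got {side}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = side // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    dx, dy = np.meshgrid(ax, ax)
    w = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    return w / w.sum()


def local_contrast(image, window: np.ndarray | None = None) -> np.ndarray:
    """Local variance-to-mean contrast field of a gray image.

    Computes ``C = (w*I^2 - (w*I)^2) / (w*I + eps)`` per pixel with reflect
    padding at the borders.  Output has the same shape as the input and is
    non-negative up to floating-point rounding.
    """
    I = _as_array(image)
    if I.ndim != 2:
        raise ValueError("local_contrast expects a 2-D image")
    if window is None:
        window = gaussian_window()
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] % 2 == 0:
        raise ValueError("filter window must be square with odd side")

    # Gaussian windows are symmetric, so correlation equals convolution; use
    # correlate to keep the weight/pixel alignment explicit.
    mean = ndimage.correlate(I, w, mode="reflect")
    mean_sq = ndimage.correlate(I * I, w, mode="reflect")
    variance = mean_sq - mean * mean
    return variance / (mean + MEAN_EPSILON)
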