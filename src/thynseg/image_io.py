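"""Grayscale raster I/O, normalization, cropping, and histograms.

All pipeline stages operate on a common currency: a 2-D ``float64`` array
with intensities in ``[0, 1]`` ("gray image").  Integer files are rescaled
by their dtype maximum on load; 8-bit quantization happens only at the I/O
boundary.  Coordinates are row-major and 0-based throughout the package.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["load_gray", "save_gray", "as_gray", "crop", "histogram"]

#: Rec. 601 luma weights used to collapse RGB captures to grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Minimum side length for an image entering the pipeline.
MIN_SIDE = 8


def as_gray(arr: np.ndarray, *, min_side: int = 1) -> np.ndarray:
    """Validate/convert an array to the internal gray-image representation.

    Accepts 2-D (gray) or 3-D (RGB/RGBA, collapsed via Rec. 601 luminance)
    arrays.  Integer dtypes are rescaled by their dtype maximum; float
    inputs are clipped to ``[0, 1]``.

    Parameters
    ----------
    arr:
        Input raster.
    min_side:
        Minimum allowed height and width.

    Returns
    -------
    2-D ``float64`` array with values in ``[0, 1]``.
    """
    a = np.asarray(arr)
    if a.size == 0:
        raise ValueError("empty raster")
    if a.ndim == 3:
        if a.shape[2] not in (3, 4):
            raise ValueError(f"expected RGB/RGBA last axis, got shape {a.shape}")
        a = a[..., :3].astype(np.float64) @ _LUMA
        if np.issubdtype(np.asarray(arr).dtype, np.integer):
            a = a / np.iinfo(np.asarray(arr).dtype).max
    elif a.ndim == 2:
        if np.issubdtype(a.dtype, np.integer):
            a = a.astype(np.float64) / np.iinfo(a.dtype).max
        else:
            a = a.astype(np.float64)
    else:
        raise ValueError(f"expected 2-D or 3-D raster, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite pixel values")
    a = np.clip(a, 0.0, 1.0)
    if a.shape[0] < min_side or a.shape[1] < min_side:
        raise ValueError(
            f"image {a.shape} smaller than minimum side {min_side}"
        )
    return a


def load_gray(path) -> np.ndarray:
    """Read a PNG/TIFF/PGM file as a gray image in ``[0, 1]``.

    RGB inputs are collapsed to luminance; integer dtypes rescaled by the
    dtype maximum; float inputs clipped to ``[0, 1]``.
    """
    raw = iio.imread(path)
    return as_gray(raw)


def save_gray(path, img: np.ndarray) -> None:
    """Write a gray image as an 8-bit grayscale file (format from suffix)."""
    img = as_gray(img)
    q = np.round(img * 255.0).astype(np.uint8)
    iio.imwrite(path, q)


def crop(img: np.ndarray, top: int, left: int, size: int) -> np.ndarray:
    """Extract a ``size`` × ``size`` window with corner ``(top, left)``.

    No resampling; the window must lie fully inside the image.
    """
    img = np.asarray(img)
    h, w = img.shape
    if size < 1:
        raise ValueError("crop size must be >= 1")
    if top < 0 or left < 0 or top + size > h or left + size > w:
        raise ValueError(
            f"crop window ({top}:{top + size}, {left}:{left + size}) "
            f"outside image of shape {img.shape}"
        )
    return img[top:top + size, left:left + size].copy()


def histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram of a gray image.

    Pixel ``p`` contributes to bin ``floor(p*255 + 0.5)``; the counts sum
    to the pixel count.
    """
    img = as_gray(img)
    bins = np.floor(img * 255.0 + 0.5).astype(np.intp)
    return np.bincount(bins.ravel(), minlength=256)
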