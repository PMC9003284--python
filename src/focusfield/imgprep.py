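"""Image loading and preprocessing.

Produces the normalized gray matrix ``gamma`` consumed by both the
ternary-pattern descriptor and the pulse-coupled network: grayscale
conversion (ITU-R BT.601 luminance), median filtering for impulse-noise
robustness, and affine normalization to [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import InvalidImageError, InvalidParameterError

#: ITU-R BT.601 luminance weights for RGB collapse.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MIN_SIDE = 3  # the descriptor needs a 3x3 neighborhood


def validate_raster(img: np.ndarray) -> np.ndarray:
    """Check raster invariants and return the array as float64.

    Accepts 2-D grayscale or (H, W, 3)/(H, W, 4) color arrays; alpha is
    dropped. Raises :class:`InvalidImageError` on anything smaller than
    3x3, non-finite, or negative.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise InvalidImageError(
            f"expected 2-D grayscale or (H, W, 3) RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise InvalidImageError(
            f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape[:2]}"
        )
    if arr.size == 0:
        raise InvalidImageError("empty image")
    if not np.all(np.isfinite(arr)):
        raise InvalidImageError("image contains non-finite samples")
    if np.any(arr < 0):
        raise InvalidImageError("image contains negative samples")
    return arr


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file into a validated float array.

    Integer inputs are rescaled by their dtype range so 8-bit and 16-bit
    files land on a comparable [0, 1] scale; float files pass through.
    """
    import imageio.v3 as iio

    raw = iio.imread(path)
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        arr = raw.astype(np.float64) / scale
    else:
        arr = raw.astype(np.float64)
    return validate_raster(arr)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB raster to one channel by BT.601 luminance.

    Already-gray input passes through unchanged.
    """
    arr = validate_raster(img)
    if arr.ndim == 2:
        return arr
    return arr @ LUMA_WEIGHTS


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median-filter with edge replication; ``window`` must be odd >= 3."""
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"median window must be odd and >= 3, got {window}")
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidImageError("median_filter expects a single-channel image")
    return ndimage.median_filter(arr, size=window, mode="nearest")


def normalize(img: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]: (x - min) / (max - min).

    A constant image has no dynamic range; it is mapped to all-zeros and
    a warning is emitted so degenerate inputs still flow downstream.
    """
    arr = np.asarray(img, dtype=np.float64)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        warnings.warn(
            "constant image: normalization is undefined, returning all-zeros",
            stacklevel=2,
        )
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def preprocess(img: np.ndarray, median_window: int = 3) -> np.ndarray:
    """Full preprocessing chain: grayscale -> median filter -> normalize."""
    return normalize(median_filter(to_grayscale(img), median_window))


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Clip a [0, 1] float image to 8-bit for export."""
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def save_image(path, img: np.ndarray) -> None:
    """Write a float [0, 1] or boolean image as 8-bit PNG."""
    import imageio.v3 as iio

    if img.dtype == bool:
        out = img.astype(np.uint8) * 255
    else:
        out = to_uint8(img)
    iio.imwrite(path, out)
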