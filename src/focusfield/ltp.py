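"""Local binary / ternary pattern descriptor and the sharpness map.

A ternary code compares each of P circular neighbors against the center
pixel with a dead-zone threshold t: differences >= t code +1, <= -t code
-1, anything in between codes 0. The ternary code splits into two binary
codes — the *upper* pattern keeps the +1s, the *lower* pattern keeps the
-1s — each labeled by the uniform rotation-invariant scheme (codes with
more than two circular 0/1 transitions pool into a single non-uniform
label, NUP). Sharp, in-focus texture is dominated by the high-count
uniform labels and the non-uniform label, so the per-pixel fraction of
those labels inside a sliding window — averaged over the upper and lower
maps — is the sharpness score.

Neighbor convention: neighbor n sits at angle 2*pi*n/P counterclockwise
from east (image rows increase downward), weighted 2**n; off-grid
neighbors are sampled by bilinear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .errors import InvalidImageError, InvalidParameterError

__all__ = [
    "DescriptorConfig",
    "CodeMaps",
    "BlurMaskedImage",
    "lbp_code",
    "ltp_code",
    "codes_from_samples",
    "ternary_to_codes",
    "uniform_label",
    "uniform_lut",
    "code_maps",
    "sharpness_map",
    "blur_mask",
]


def _default_sharp_bins(p: int = 8) -> frozenset:
    # high-count uniform labels plus the non-uniform bin; NUP = p + 1
    return frozenset({6, 7, 8, p + 1})


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameters of the descriptor and the sliding sharpness window."""

    neighbors: int = 8
    radius: float = 1.0
    threshold: float = 0.02  # ternary dead-zone on the [0, 1] gray scale
    window: int = 33
    sharp_bins: frozenset = field(default_factory=_default_sharp_bins)

    def __post_init__(self):
        if self.neighbors <= 0:
            raise InvalidParameterError("neighbors must be positive")
        if self.radius <= 0:
            raise InvalidParameterError("radius must be positive")
        if self.threshold <= 0:
            raise InvalidParameterError("ternary threshold must be > 0")
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidParameterError("window must be odd and >= 3")
        legal = set(range(self.neighbors + 1)) | {self.nup_label}
        if not set(self.sharp_bins) <= legal:
            raise InvalidParameterError(f"sharp_bins must be a subset of {sorted(legal)}")

    @property
    def nup_label(self) -> int:
        """Sentinel label for non-uniform patterns."""
        return self.neighbors + 1


@dataclass
class CodeMaps:
    """Per-pixel upper/lower binary codes and their uniform labels."""

    upper: np.ndarray
    lower: np.ndarray
    upper_label: np.ndarray
    lower_label: np.ndarray


@dataclass
class BlurMaskedImage:
    """Image with blur-classified pixels zeroed; sharp_mask marks the rest."""

    pixels: np.ndarray
    sharp_mask: np.ndarray


def neighbor_offsets(p: int, r: float) -> np.ndarray:
    """(p, 2) array of (row, col) offsets, n = 0 east, counterclockwise.

    Offsets within 1e-9 of the integer grid are snapped so axis-aligned
    neighbors are sampled exactly.
    """
    n = np.arange(p)
    ang = 2.0 * np.pi * n / p
    off = np.stack([-r * np.sin(ang), r * np.cos(ang)], axis=1)
    snapped = np.round(off)
    off[np.abs(off - snapped) < 1e-9] = snapped[np.abs(off - snapped) < 1e-9]
    return off


def sample_neighbors(img: np.ndarray, p: int, r: float) -> np.ndarray:
    """Bilinearly sample the p circular neighbors of every pixel.

    Returns a (p, H, W) stack; coordinates outside the image are clamped
    to the nearest edge pixel (replication, consistent with the filter
    border policy).
    """
    arr = np.asarray(img, dtype=np.float64)
    h, w = arr.shape
    pad = int(np.ceil(r)) + 1
    padded = np.pad(arr, pad, mode="edge")
    rows = np.arange(h)[:, None] + pad
    cols = np.arange(w)[None, :] + pad
    out = np.empty((p, h, w), dtype=np.float64)
    for k, (dy, dx) in enumerate(neighbor_offsets(p, r)):
        y = rows + dy
        x = cols + dx
        y0 = np.floor(y).astype(np.intp)
        x0 = np.floor(x).astype(np.intp)
        fy = y - y0
        fx = x - x0
        v00 = padded[y0, x0]
        v01 = padded[y0, x0 + 1]
        v10 = padded[y0 + 1, x0]
        v11 = padded[y0 + 1, x0 + 1]
        # difference form: exact on constant patches (weights need not
        # sum to one bit-exactly)
        out[k] = v00 + fx * (v01 - v00) + fy * (v10 - v00) + fy * fx * (
            v11 - v10 - v01 + v00
        )
    return out


def codes_from_samples(center: float, samples, threshold: float):
    """Upper/lower codes from explicit neighbor sample values.

    ``samples[n]`` is the value of neighbor n (bit weight 2**n). The
    ternary rule assigns +1 when sample - center >= threshold, -1 when
    <= -threshold, else 0; the two signs populate the two binary codes.
    """
    if threshold <= 0:
        raise InvalidParameterError("ternary threshold must be > 0")
    d = np.asarray(samples, dtype=np.float64) - float(center)
    weights = 1 << np.arange(d.size)
    upper = int(np.sum(weights[d >= threshold]))
    lower = int(np.sum(weights[d <= -threshold]))
    return upper, lower


def ternary_to_codes(ternary) -> tuple:
    """Upper/lower binary codes from a raw ternary vector in {-1, 0, 1}."""
    t = np.asarray(ternary)
    weights = 1 << np.arange(t.size)
    return int(np.sum(weights[t == 1])), int(np.sum(weights[t == -1]))


def _center_samples(patch: np.ndarray, cfg: DescriptorConfig):
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 2 * int(np.ceil(cfg.radius)) + 1:
        raise InvalidImageError(
            f"neighborhood too small for radius {cfg.radius}: {patch.shape}"
        )
    cy, cx = patch.shape[0] // 2, patch.shape[1] // 2
    stack = sample_neighbors(patch, cfg.neighbors, cfg.radius)
    return patch[cy, cx], stack[:, cy, cx]


def lbp_code(patch: np.ndarray, cfg: DescriptorConfig = DescriptorConfig()) -> int:
    """Binary code at the center of ``patch``: bit n = 1 iff neighbor n >= center."""
    center, samples = _center_samples(patch, cfg)
    weights = 1 << np.arange(cfg.neighbors)
    return int(np.sum(weights[samples - center >= 0]))


def ltp_code(patch: np.ndarray, cfg: DescriptorConfig = DescriptorConfig()) -> tuple:
    """(upper, lower) ternary-split codes at the center of ``patch``."""
    center, samples = _center_samples(patch, cfg)
    return codes_from_samples(center, samples, cfg.threshold)


@lru_cache(maxsize=None)
def uniform_lut(p: int) -> np.ndarray:
    """Label table for all 2**p codes: popcount if <= 2 circular
    transitions, else the non-uniform sentinel p + 1."""
    codes = np.arange(1 << p, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(p)[None, :]) & 1
    transitions = np.sum(bits != np.roll(bits, 1, axis=1), axis=1)
    ones = bits.sum(axis=1)
    return np.where(transitions <= 2, ones, p + 1).astype(np.int32)


def uniform_label(code: int, p: int) -> int:
    """Uniform rotation-invariant label of a single p-bit code."""
    if not 0 <= code < (1 << p):
        raise InvalidParameterError(f"code {code} out of range for {p} bits")
    return int(uniform_lut(p)[code])


def code_maps(img: np.ndarray, cfg: DescriptorConfig = DescriptorConfig()) -> CodeMaps:
    """Vectorized upper/lower code and label maps for a whole image."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidImageError("code_maps expects a single-channel image")
    samples = sample_neighbors(arr, cfg.neighbors, cfg.radius)
    d = samples - arr[None, :, :]
    weights = (1 << np.arange(cfg.neighbors)).astype(np.int64)[:, None, None]
    upper = np.sum(np.where(d >= cfg.threshold, weights, 0), axis=0)
    lower = np.sum(np.where(d <= -cfg.threshold, weights, 0), axis=0)
    lut = uniform_lut(cfg.neighbors)
    return CodeMaps(upper, lower, lut[upper], lut[lower])


def sharpness_map(
    img: np.ndarray, cfg: DescriptorConfig = DescriptorConfig()
) -> np.ndarray:
    """Per-pixel sharpness in [0, 1].

    For each of the upper and lower label maps, the windowed fraction of
    pixels whose label falls in ``cfg.sharp_bins``; the two fractions are
    averaged (the upper/lower fusion). Window larger than the image is
    clipped with a warning.
    """
    arr = np.asarray(img, dtype=np.float64)
    window = cfg.window
    if window > min(arr.shape):
        window = min(arr.shape)
        if window % 2 == 0:
            window -= 1
        warnings.warn(
            f"sharpness window {cfg.window} exceeds image extent, clipped to {window}",
            stacklevel=2,
        )
    maps = code_maps(arr, cfg)
    bins = np.array(sorted(cfg.sharp_bins))
    frac = np.zeros_like(arr)
    for labels in (maps.upper_label, maps.lower_label):
        ind = np.isin(labels, bins).astype(np.float64)
        frac += ndimage.uniform_filter(ind, size=window, mode="nearest")
    return np.clip(frac / 2.0, 0.0, 1.0)


def blur_mask(img: np.ndarray, sharpness: np.ndarray, threshold: float) -> BlurMaskedImage:
    """Zero out pixels classified as blurred (sharpness below threshold)."""
    arr = np.asarray(img, dtype=np.float64)
    s = np.asarray(sharpness, dtype=np.float64)
    if arr.shape != s.shape:
        raise InvalidImageError(
            f"image shape {arr.shape} != sharpness shape {s.shape}"
        )
    sharp = s >= threshold
    return BlurMaskedImage(np.where(sharp, arr, 0.0), sharp)
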