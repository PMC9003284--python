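"""Seeded synthetic partially-blurred images with ground-truth masks.

Each fixture renders a band-limited noise texture over the full frame,
Gaussian-blurs everything outside a foreground geometry (disk, ring,
blob, polygon), adds sensor noise, and returns the generating geometry
as the ground-truth mask (sharp = True/white, blurred = False/black).
Identical spec + seed yields bit-identical pixels.

Besides the generic partial-blur generator there are two microscopy-like
presets: ``seed_ring`` (an annulus of sharp texture with blurred
interior and exterior, like a round plant seed whose rim is in focus)
and ``paramecium`` (an elongated sharp blob over a blurred background
scattered with out-of-focus organisms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = ["FixtureSpec", "make_partial_blur", "make_microscopy_like", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    shape: tuple = (256, 256)
    foreground: str = "disk"  # disk | ring | blob | polygon
    texture_contrast: float = 0.3
    texture_scale: float = 0.6  # smoothing sigma of the band-limited noise
    blur_sigma: float = 3.0
    noise_sigma: float = 0.01
    seed: int = 0
    radius_frac: float = 0.30  # outer radius relative to min(shape)
    inner_frac: float = 0.55  # ring: inner radius as fraction of outer

    def __post_init__(self):
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise InvalidParameterError("sigmas must be non-negative")
        if self.foreground not in ("disk", "ring", "blob", "polygon"):
            raise InvalidParameterError(f"unknown foreground {self.foreground!r}")
        if len(self.shape) != 2 or min(self.shape) < 16:
            raise InvalidParameterError("shape must be 2-D, at least 16x16")


def _texture(shape, contrast, scale, rng) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if scale > 0:
        noise = ndimage.gaussian_filter(noise, scale, mode="nearest")
        noise /= max(noise.std(), 1e-12)
    return np.clip(0.5 + 0.5 * contrast * noise, 0.02, 0.98)


def _geometry(spec: FixtureSpec) -> np.ndarray:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_out = spec.radius_frac * min(h, w)
    if spec.foreground == "disk":
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_out**2
    if spec.foreground == "ring":
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        return (r2 <= r_out**2) & (r2 >= (spec.inner_frac * r_out) ** 2)
    if spec.foreground == "blob":
        theta = np.deg2rad(25.0)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        return (u / (1.15 * r_out)) ** 2 + (v / (0.45 * r_out)) ** 2 <= 1.0
    # polygon: regular hexagon
    ang = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    apothem = r_out * np.cos(np.pi / 6)
    sector = np.mod(ang, np.pi / 3) - np.pi / 6
    return rad * np.cos(sector) <= apothem


def _compose(spec: FixtureSpec, mask: np.ndarray, texture: np.ndarray, rng) -> np.ndarray:
    frac = mask.mean()
    if frac < 0.05 or frac > 0.95:
        raise InvalidParameterError(
            f"foreground covers {frac:.1%} of the frame; both classes need >= 5%"
        )
    if spec.blur_sigma > 0:
        blurred = ndimage.gaussian_filter(texture, spec.blur_sigma, mode="nearest")
    else:
        blurred = texture
    img = np.where(mask, texture, blurred)
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal(spec.shape)
    return np.clip(img, 0.0, 1.0)


def make_partial_blur(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, ground-truth mask) for a generic partial-blur scene."""
    rng = np.random.default_rng(spec.seed)
    texture = _texture(spec.shape, spec.texture_contrast, spec.texture_scale, rng)
    mask = _geometry(spec)
    return _compose(spec, mask, texture, rng), mask


def make_microscopy_like(kind: str, spec: FixtureSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Microscopy-flavoured fixtures: ``seed_ring`` or ``paramecium``."""
    if spec is None:
        spec = FixtureSpec()
    if kind == "seed_ring":
        return make_partial_blur(replace(spec, foreground="ring", radius_frac=0.36))
    if kind == "paramecium":
        spec = replace(spec, foreground="blob")
        rng = np.random.default_rng(spec.seed)
        texture = _texture(spec.shape, spec.texture_contrast, spec.texture_scale, rng)
        # scatter dim out-of-focus organisms into the background texture
        h, w = spec.shape
        backdrop = texture.copy()
        for _ in range(6):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            r = rng.integers(max(4, h // 32), max(6, h // 12))
            yy, xx = np.mgrid[0:h, 0:w]
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            backdrop[blob] = np.clip(backdrop[blob] + rng.uniform(-0.25, 0.25), 0.02, 0.98)
        mask = _geometry(spec)
        img = np.where(mask, texture, backdrop)
        spec2 = replace(spec)
        out = _compose(spec2, mask, img, rng)
        return out, mask
    raise InvalidParameterError(f"unknown microscopy fixture kind {kind!r}")


def write_fixture(out_dir, name: str, img: np.ndarray, mask: np.ndarray, spec: FixtureSpec) -> None:
    """Write image + mask PNG pair and a JSON manifest next to them."""
    from pathlib import Path

    from .imgprep import save_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image(out / f"{name}.png", img)
    save_image(out / f"{name}_mask.png", mask)
    manifest = asdict(spec)
    manifest["shape"] = list(spec.shape)
    (out / f"{name}.json").write_text(json.dumps(manifest, indent=2))
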