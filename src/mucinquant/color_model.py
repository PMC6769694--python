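"""Raster types and HSV color geometry shared by both segmentation backends.

Hue is expressed in degrees in [0, 360); saturation and value as fractions
in [0, 1]. Achromatic pixels (S = 0) carry hue 0 by convention and can only
be selected through saturation/value bounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

logger = logging.getLogger(__name__)

__all__ = [
    "RGBImage",
    "HSVImage",
    "HSVRange",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "hue_in_range",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
]


@dataclass(frozen=True)
class RGBImage:
    """8-bit RGB raster of one microscope field.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array of integer channel values in [0, 255].
        Stored internally as contiguous ``uint8``.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected an (height, width, 3) raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("raster must contain at least one pixel")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"channel values must be integers, got dtype {px.dtype}")
        if int(px.min()) < 0 or int(px.max()) > 255:
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel hue (degrees), saturation and value (fractions) planes."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        h, s, v = (np.asarray(a, dtype=float) for a in (self.hue, self.saturation, self.value))
        if not (h.shape == s.shape == v.shape) or h.ndim != 2:
            raise ValueError("hue/saturation/value must be matching 2-D planes")
        if h.min() < 0.0 or h.max() >= 360.0:
            raise ValueError("hue must lie in [0, 360)")
        for name, plane in (("saturation", s), ("value", v)):
            if plane.min() < 0.0 or plane.max() > 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        object.__setattr__(self, "hue", h)
        object.__setattr__(self, "saturation", s)
        object.__setattr__(self, "value", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class HSVRange:
    """Per-channel acceptance interval; the hue interval may wrap across 0°.

    ``hue_lo > hue_hi`` denotes an interval crossing the 360°/0° seam, e.g.
    ``[330, 30]`` accepts hues ≥ 330° or ≤ 30°. The bound 360 is accepted so
    that ``HSVRange(0, 360, ...)`` covers every hue.
    """

    hue_lo: float
    hue_hi: float
    sat_lo: float
    sat_hi: float
    val_lo: float
    val_hi: float

    def __post_init__(self) -> None:
        for name in ("hue_lo", "hue_hi"):
            h = getattr(self, name)
            if not 0.0 <= h <= 360.0:
                raise ValueError(f"{name}={h} outside [0, 360]")
        if not 0.0 <= self.sat_lo <= self.sat_hi <= 1.0:
            raise ValueError("require 0 <= sat_lo <= sat_hi <= 1")
        if not 0.0 <= self.val_lo <= self.val_hi <= 1.0:
            raise ValueError("require 0 <= val_lo <= val_hi <= 1")

    def to_dict(self) -> dict[str, float]:
        return {
            "hue_lo": self.hue_lo,
            "hue_hi": self.hue_hi,
            "sat_lo": self.sat_lo,
            "sat_hi": self.sat_hi,
            "val_lo": self.val_lo,
            "val_hi": self.val_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HSVRange":
        return cls(**{k: float(d[k]) for k in (
            "hue_lo", "hue_hi", "sat_lo", "sat_hi", "val_lo", "val_hi")})


def rgb_to_hsv(image: RGBImage) -> HSVImage:
    """Standard hexcone RGB→HSV conversion, applied per pixel.

    Returns hue in degrees [0, 360), saturation and value in [0, 1];
    achromatic pixels get hue 0.
    """
    if not isinstance(image, RGBImage):
        image = RGBImage(np.asarray(image))
    hsv = _skcolor.rgb2hsv(image.pixels)
    hue = (hsv[..., 0] * 360.0) % 360.0
    return HSVImage(hue=hue, saturation=hsv[..., 1], value=hsv[..., 2])


def hsv_to_rgb(image: HSVImage) -> RGBImage:
    """Inverse hexcone conversion back to an 8-bit RGB raster."""
    hsv = np.stack([image.hue / 360.0, image.saturation, image.value], axis=-1)
    rgb = _skcolor.hsv2rgb(hsv)
    return RGBImage(np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8))


def hue_in_range(hue: Union[float, np.ndarray], rng: HSVRange) -> Union[bool, np.ndarray]:
    """Membership of hue(s) in the possibly wrapping closed hue interval.

    Works elementwise on arrays; scalars return a plain bool.
    """
    h = np.asarray(hue, dtype=float)
    if h.size and (h.min() < 0.0 or h.max() >= 360.0):
        raise ValueError("hue must lie in [0, 360)")
    if rng.hue_lo <= rng.hue_hi:
        out = (h >= rng.hue_lo) & (h <= rng.hue_hi)
    else:  # interval crosses the 0° seam
        out = (h >= rng.hue_lo) | (h <= rng.hue_hi)
    if np.isscalar(hue) or np.ndim(hue) == 0:
        return bool(out)
    return out


def read_image(path: Union[str, Path]) -> RGBImage:
    """Read an 8-bit RGB PNG/TIFF/JPEG field image.

    JPEG inputs are accepted with a logged warning, as lossy compression can
    bias per-pixel color statistics. Fully opaque RGBA rasters are flattened
    to RGB; anything else with a channel count other than 3 is rejected.
    """
    p = Path(path)
    if p.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning(
            "%s: JPEG compression artifacts may bias pixel color statistics", p
        )
    arr = iio.imread(p)
    if arr.ndim == 3 and arr.shape[2] == 4:
        if np.all(arr[..., 3] == 255):
            arr = arr[..., :3]
        else:
            raise ValueError(f"{p}: RGBA raster with non-trivial alpha not supported")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{p}: expected a 3-channel RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{p}: only 8-bit rasters supported, got dtype {arr.dtype}")
    return RGBImage(arr)


def write_image(path: Union[str, Path], image: RGBImage) -> None:
    iio.imwrite(Path(path), image.pixels)


def write_label_mask(path: Union[str, Path], labels: np.ndarray) -> None:
    """Write a per-pixel class-label mask as a single-channel 8-bit PNG."""
    lab = np.asarray(labels)
    if lab.ndim != 2:
        raise ValueError("label mask must be 2-D")
    iio.imwrite(Path(path), lab.astype(np.uint8))


def read_label_mask(path: Union[str, Path]) -> np.ndarray:
    lab = iio.imread(Path(path))
    if lab.ndim != 2:
        raise ValueError(f"{path}: label mask must be single-channel")
    return lab.astype(np.uint8)
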