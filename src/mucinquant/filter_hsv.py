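"""HSV-threshold segmentation backend.

A pixel is counted as histochemical reaction when its hue, saturation and
value all fall inside the configured acceptance ranges and it is not glass
background; the area fraction is

    A% = reaction pixels / tissue pixels × 100

with tissue defined as every non-background pixel (reaction included).

The stain presets below are calibration choices for typical PAS (magenta)
and alcian blue reactions, not published thresholds; every bound can be
overridden via config.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from skimage import morphology as _skmorph

from .color_model import HSVImage, HSVRange, RGBImage, hue_in_range, rgb_to_hsv

logger = logging.getLogger(__name__)

__all__ = [
    "PAS_REACTION_RANGE",
    "AB_REACTION_RANGE",
    "FilterHSVConfig",
    "FieldResult",
    "EmptyFieldError",
    "background_mask",
    "segment_reaction_hsv",
    "field_area_fraction_hsv",
]

#: Magenta PAS reaction product (calibration default).
PAS_REACTION_RANGE = HSVRange(280.0, 345.0, 0.15, 1.0, 0.15, 0.95)
#: Blue alcian blue reaction product (calibration default).
AB_REACTION_RANGE = HSVRange(180.0, 260.0, 0.15, 1.0, 0.15, 0.95)

_STAIN_PRESETS = {"pas": PAS_REACTION_RANGE, "ab": AB_REACTION_RANGE}


class EmptyFieldError(ValueError):
    """Raised when a field contains no tissue pixels (A% undefined)."""


@dataclass(frozen=True)
class FilterHSVConfig:
    """Thresholds driving HSV segmentation of one stain.

    Background (glass) is bright and unsaturated: saturation below
    ``background_sat_max`` and value above ``background_val_min``.
    ``min_object_px`` enables an optional small-object filter on the
    reaction mask; 0 (default) applies pure thresholding.
    """

    reaction_range: HSVRange
    background_sat_max: float = 0.10
    background_val_min: float = 0.85
    stain: str = "custom"
    min_object_px: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_sat_max <= 1.0:
            raise ValueError("background_sat_max must lie in [0, 1]")
        if not 0.0 <= self.background_val_min <= 1.0:
            raise ValueError("background_val_min must lie in [0, 1]")
        if self.stain not in {"pas", "ab", "custom"}:
            raise ValueError(f"unknown stain {self.stain!r}")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")

    @classmethod
    def for_stain(cls, stain: str, **overrides) -> "FilterHSVConfig":
        """Preset config for ``pas`` or ``ab``; keyword overrides applied on top."""
        key = stain.lower()
        if key not in _STAIN_PRESETS:
            raise ValueError(f"no preset for stain {stain!r}; use 'pas' or 'ab'")
        cfg = cls(reaction_range=_STAIN_PRESETS[key], stain=key)
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "FilterHSVConfig":
        """Load from a YAML file with explicit range and background keys.

        Recognised keys: ``stain`` (preset base), the six range bounds
        ``hue_lo .. val_hi``, ``background_sat_max``, ``background_val_min``,
        ``min_object_px``. Explicit bounds override the preset.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stain = str(raw.get("stain", "custom")).lower()
        if stain in _STAIN_PRESETS:
            base = _STAIN_PRESETS[stain].to_dict()
        else:
            base = {}
        bounds = ("hue_lo", "hue_hi", "sat_lo", "sat_hi", "val_lo", "val_hi")
        for k in bounds:
            if k in raw:
                base[k] = float(raw[k])
        missing = [k for k in bounds if k not in base]
        if missing:
            raise ValueError(f"config {path}: missing range bounds {missing}")
        return cls(
            reaction_range=HSVRange.from_dict(base),
            background_sat_max=float(raw.get("background_sat_max", 0.10)),
            background_val_min=float(raw.get("background_val_min", 0.85)),
            stain=stain if stain in _STAIN_PRESETS else "custom",
            min_object_px=int(raw.get("min_object_px", 0)),
        )

    def to_dict(self) -> dict:
        d = self.reaction_range.to_dict()
        d.update(
            background_sat_max=self.background_sat_max,
            background_val_min=self.background_val_min,
            stain=self.stain,
            min_object_px=self.min_object_px,
        )
        return d


@dataclass(frozen=True)
class FieldResult:
    """Per-field pixel counts and area fraction from one backend."""

    reaction_pixels: int
    tissue_pixels: int
    background_pixels: int
    area_fraction_percent: float
    backend: str
    stain: str
    field_id: str = ""

    def __post_init__(self) -> None:
        if self.reaction_pixels > self.tissue_pixels:
            raise ValueError("reaction pixels cannot exceed tissue pixels")
        if not 0.0 <= self.area_fraction_percent <= 100.0:
            raise ValueError("area fraction must lie in [0, 100]")


def background_mask(hsv: HSVImage, config: FilterHSVConfig) -> np.ndarray:
    """Boolean mask of glass background: unsaturated and bright."""
    return (hsv.saturation < config.background_sat_max) & (
        hsv.value > config.background_val_min
    )


def segment_reaction_hsv(hsv: HSVImage, config: FilterHSVConfig) -> np.ndarray:
    """Boolean reaction mask: in all three HSV ranges and not background."""
    r = config.reaction_range
    mask = (
        hue_in_range(hsv.hue, r)
        & (hsv.saturation >= r.sat_lo)
        & (hsv.saturation <= r.sat_hi)
        & (hsv.value >= r.val_lo)
        & (hsv.value <= r.val_hi)
        & ~background_mask(hsv, config)
    )
    if config.min_object_px > 1:
        mask = _skmorph.remove_small_objects(mask, min_size=config.min_object_px)
    return mask


def field_area_fraction_hsv(
    image: RGBImage, config: FilterHSVConfig, field_id: str = "field"
) -> FieldResult:
    """Segment one field and report its tissue-relative area fraction."""
    hsv = rgb_to_hsv(image)
    bg = background_mask(hsv, config)
    tissue = int((~bg).sum())
    if tissue == 0:
        raise EmptyFieldError(f"empty field (no tissue pixels): {field_id}")
    reaction = int(segment_reaction_hsv(hsv, config).sum())
    return FieldResult(
        reaction_pixels=reaction,
        tissue_pixels=tissue,
        background_pixels=int(bg.sum()),
        area_fraction_percent=100.0 * reaction / tissue,
        backend="filter_hsv",
        stain=config.stain,
        field_id=field_id,
    )
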