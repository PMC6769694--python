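"""Seeded three-class pixel classification backend.

Every pixel is assigned to one of three color classes — 1: reaction,
2: tissue without reaction, 3: background — by a quadratic discriminant
(per-class Gaussian with full covariance, equal priors). Seed pixels
replace the interactive training step of commercial tools. The area
fraction is computed from class counts:

    A% = class-1 pixels / (class-1 + class-2 pixels) × 100

so class-3 (background) pixels never influence the result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .color_model import RGBImage, rgb_to_hsv
from .filter_hsv import EmptyFieldError, FieldResult

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_REACTION",
    "CLASS_TISSUE",
    "CLASS_BACKGROUND",
    "ColorClassModel",
    "MissingClassSeedsError",
    "fit_color_classes",
    "classify_pixels",
    "class_counts",
    "field_area_fraction_classes",
    "seeds_from_coords",
    "seeds_from_truth",
    "label_overlay",
]

CLASS_REACTION = 1
CLASS_TISSUE = 2
CLASS_BACKGROUND = 3
_CLASS_NAMES = {1: "reaction", 2: "tissue", 3: "background"}

#: Overlay palette: green = reaction, yellow = tissue, black = background.
_OVERLAY_COLORS = {1: (0, 200, 0), 2: (230, 220, 0), 3: (0, 0, 0)}


class MissingClassSeedsError(ValueError):
    """Raised when a class has no seed pixels to fit from."""


@dataclass(frozen=True)
class ColorClassModel:
    """Fitted per-class color statistics for the quadratic discriminant.

    ``means`` is (3, 3) and ``covariances`` (3, 3, 3), ordered by class
    index 1..3. ``epsilon`` is the ridge added to every covariance diagonal
    (on the 0–255 channel scale) so single-color classes stay usable.
    """

    means: np.ndarray
    covariances: np.ndarray
    epsilon: float
    color_space: str = "rgb"

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        c = np.asarray(self.covariances, dtype=float)
        if m.shape != (3, 3) or c.shape != (3, 3, 3):
            raise ValueError("model requires exactly three classes of 3-D color stats")
        if self.color_space not in {"rgb", "hsv-cartesian"}:
            raise ValueError(f"unknown color space {self.color_space!r}")
        for k in range(3):
            if not np.allclose(c[k], c[k].T):
                raise ValueError(f"class {k + 1} covariance not symmetric")
            if np.any(np.linalg.eigvalsh(c[k]) <= 0):
                raise ValueError(f"class {k + 1} covariance not positive-definite")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)


def _features(pixels: np.ndarray, color_space: str) -> np.ndarray:
    """Map (N, 3) RGB rows to classification features."""
    px = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if color_space == "rgb":
        return px
    # hue-wraparound-free cylindrical coordinates, rescaled to the 0-255 range
    hsv = rgb_to_hsv(RGBImage(np.clip(np.rint(px), 0, 255).astype(np.uint8)[None, :, :]))
    h = np.deg2rad(hsv.hue.ravel())
    s = hsv.saturation.ravel()
    v = hsv.value.ravel()
    return 255.0 * np.column_stack([s * np.cos(h), s * np.sin(h), v])


def fit_color_classes(
    seeds: Mapping[int, Sequence],
    epsilon: float = 1.0,
    color_space: str = "rgb",
) -> ColorClassModel:
    """Fit per-class mean and ridge-regularized covariance from seed pixels.

    Parameters
    ----------
    seeds
        Mapping from class index (1, 2, 3) to an array-like of RGB seed
        pixels, shape (n, 3).
    epsilon
        Ridge added to each covariance diagonal; keeps one-seed classes
        non-singular.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    means = np.empty((3, 3))
    covs = np.empty((3, 3, 3))
    for cls in (CLASS_REACTION, CLASS_TISSUE, CLASS_BACKGROUND):
        raw = seeds.get(cls)
        if raw is None or len(raw) == 0:
            raise MissingClassSeedsError(
                f"no seed pixels for class {cls} ({_CLASS_NAMES[cls]})"
            )
        feats = _features(np.asarray(raw), color_space)
        means[cls - 1] = feats.mean(axis=0)
        if feats.shape[0] > 1:
            covs[cls - 1] = np.cov(feats, rowvar=False, ddof=1)
        else:
            covs[cls - 1] = np.zeros((3, 3))
        covs[cls - 1] += epsilon * np.eye(3)
    return ColorClassModel(means=means, covariances=covs, epsilon=epsilon, color_space=color_space)


def classify_pixels(image: RGBImage, model: ColorClassModel) -> np.ndarray:
    """Label every pixel 1/2/3 by the highest Gaussian log-density.

    Equal priors; exact ties resolve to the lowest class index. Output is a
    ``uint8`` (height, width) label mask.
    """
    x = _features(image.pixels, model.color_space)
    scores = np.empty((x.shape[0], 3))
    for k in range(3):
        cov = model.covariances[k]
        diff = x - model.means[k]
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        _, logdet = np.linalg.slogdet(cov)
        scores[:, k] = -0.5 * (maha + logdet)
    labels = np.argmax(scores, axis=1).astype(np.uint8) + 1  # argmax -> lowest index on ties
    return labels.reshape(image.height, image.width)


def class_counts(labels: np.ndarray) -> dict[int, int]:
    lab = np.asarray(labels)
    bad = np.setdiff1d(np.unique(lab), [1, 2, 3])
    if bad.size:
        raise ValueError(f"label mask contains values outside {{1,2,3}}: {bad.tolist()}")
    return {c: int((lab == c).sum()) for c in (1, 2, 3)}


def field_area_fraction_classes(
    labels: np.ndarray, stain: str = "custom", field_id: str = "field"
) -> FieldResult:
    """Area fraction from a three-class label mask (class-count formula)."""
    counts = class_counts(labels)
    c1, c2, c3 = counts[1], counts[2], counts[3]
    if c1 + c2 == 0:
        raise EmptyFieldError(f"empty field (no class-1 or class-2 pixels): {field_id}")
    return FieldResult(
        reaction_pixels=c1,
        tissue_pixels=c1 + c2,
        background_pixels=c3,
        area_fraction_percent=100.0 * c1 / (c1 + c2),
        backend="smart_seg",
        stain=stain,
        field_id=field_id,
    )


def seeds_from_coords(
    image: RGBImage, coords: Mapping[int, Sequence[Sequence[int]]]
) -> dict[int, np.ndarray]:
    """Collect seed pixels from per-class (x, y) coordinates on an image."""
    out: dict[int, np.ndarray] = {}
    for cls, pts in coords.items():
        pts = np.asarray(pts, dtype=int).reshape(-1, 2)
        xs, ys = pts[:, 0], pts[:, 1]
        if xs.size and (
            xs.min() < 0 or ys.min() < 0 or xs.max() >= image.width or ys.max() >= image.height
        ):
            raise ValueError(f"class {cls}: seed coordinate outside the raster")
        out[int(cls)] = image.pixels[ys, xs].astype(float)
    return out


def seeds_from_truth(
    image: RGBImage,
    labels: np.ndarray,
    n_per_class: int = 200,
    rng: np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Sample up to ``n_per_class`` seed pixels per class from a label mask."""
    rng = rng or np.random.default_rng(0)
    lab = np.asarray(labels)
    seeds: dict[int, np.ndarray] = {}
    for cls in (1, 2, 3):
        ys, xs = np.nonzero(lab == cls)
        if ys.size == 0:
            continue
        take = min(n_per_class, ys.size)
        idx = rng.choice(ys.size, size=take, replace=False)
        seeds[cls] = image.pixels[ys[idx], xs[idx]].astype(float)
    return seeds


def label_overlay(labels: np.ndarray) -> RGBImage:
    """Three-color visualization of a label mask."""
    lab = np.asarray(labels)
    out = np.zeros(lab.shape + (3,), dtype=np.uint8)
    for cls, color in _OVERLAY_COLORS.items():
        out[lab == cls] = color
    return RGBImage(out)
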