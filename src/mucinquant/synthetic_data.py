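"""Synthetic stained-field and cohort generators with exact ground truth.

Fields emulate a brightfield histochemistry photomicrograph: bright glass
background, counterstained tissue (hematoxylin blue-violet for PAS,
safranin red for AB), crypt-like reaction blobs (magenta for PAS, blue for
AB), a mild multiplicative illumination gradient and per-pixel Gaussian
noise. The truth label mask (1 = reaction, 2 = tissue, 3 = background) is
exact by construction, so the emitted true area fraction equals the
class-count formula exactly.

Cohorts mimic the published cohort scale (paired tumor/control area
fractions per stain and backend, clinical covariates, exponential survival
with optional group hazard ratio) with configurable effect sizes. All
randomness flows from the explicit spec seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .color_model import RGBImage
from .quantify import pp_category

__all__ = [
    "FieldSpec",
    "FieldSample",
    "FieldSpecError",
    "generate_field",
    "generate_slide_fields",
    "CohortSpec",
    "generate_cohort",
    "COHORT_COLUMNS",
]

#: Rendering palettes per stain: (reaction, counterstained tissue, glass).
STAIN_COLORS = {
    "pas": {
        "reaction": (193, 30, 121),   # magenta Schiff product
        "tissue": (110, 90, 165),     # hematoxylin blue-violet
        "background": (246, 244, 248),
    },
    "ab": {
        "reaction": (40, 70, 190),    # alcian blue
        "tissue": (200, 90, 90),      # safranin red
        "background": (246, 244, 248),
    },
}


class FieldSpecError(ValueError):
    """Raised for unachievable or inconsistent field specifications."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic stained field."""

    height: int = 256
    width: int = 256
    target_area_fraction: float = 0.20
    stain: str = "pas"
    tissue_coverage: float = 0.70
    blob_radius: tuple[float, float] = (6.0, 28.0)
    illumination_amplitude: float = 0.05
    noise_sigma: float = 8.0
    seed: int = 0
    reaction_color: tuple[int, int, int] | None = None
    tissue_color: tuple[int, int, int] | None = None
    background_color: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise FieldSpecError("raster must be at least 8x8")
        if not 0.0 <= self.target_area_fraction <= 1.0:
            raise FieldSpecError("target_area_fraction must lie in [0, 1]")
        if self.stain not in STAIN_COLORS:
            raise FieldSpecError(f"unknown stain {self.stain!r}")
        if not 0.0 < self.tissue_coverage <= 1.0:
            raise FieldSpecError("tissue_coverage must lie in (0, 1]")
        lo, hi = self.blob_radius
        if not 0 < lo <= hi:
            raise FieldSpecError("blob_radius must satisfy 0 < lo <= hi")
        if hi > max(self.height, self.width):
            raise FieldSpecError("blobs do not fit the raster")
        if self.noise_sigma < 0:
            raise FieldSpecError("noise_sigma must be >= 0")
        if not 0.0 <= self.illumination_amplitude < 1.0:
            raise FieldSpecError("illumination_amplitude must lie in [0, 1)")

    def color(self, role: str) -> tuple[int, int, int]:
        override = getattr(self, f"{role}_color")
        return override if override is not None else STAIN_COLORS[self.stain][role]


@dataclass(frozen=True)
class FieldSample:
    """Rendered field plus its exact ground truth."""

    image: RGBImage
    labels: np.ndarray
    true_area_fraction_percent: float
    spec: FieldSpec


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _tissue_mask(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.tissue_coverage >= 0.999:
        return np.ones((spec.height, spec.width), dtype=bool)
    area = spec.tissue_coverage * spec.height * spec.width
    aspect = rng.uniform(0.75, 1.3)
    ry = np.sqrt(area * aspect / np.pi)
    rx = area / (np.pi * ry)
    cy = spec.height / 2 + rng.uniform(-0.05, 0.05) * spec.height
    cx = spec.width / 2 + rng.uniform(-0.05, 0.05) * spec.width
    mask = _ellipse_mask(spec.height, spec.width, cy, cx, ry, rx)
    if not mask.any():  # pragma: no cover - coverage>0 guarantees a pixel
        raise FieldSpecError("tissue region empty")
    return mask


def _place_reaction(
    spec: FieldSpec, tissue: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Union of random ellipses inside tissue, trimmed to the exact target count."""
    target_px = int(round(spec.target_area_fraction * int(tissue.sum())))
    reaction = np.zeros_like(tissue)
    if target_px == 0:
        return reaction
    ys, xs = np.nonzero(tissue)
    count = 0
    iters = 0
    while count < target_px:
        iters += 1
        if iters > 500:
            # sparse remainder: fill directly from still-unstained tissue
            free_ys, free_xs = np.nonzero(tissue & ~reaction)
            pick = rng.permutation(free_ys.size)[: target_px - count]
            reaction[free_ys[pick], free_xs[pick]] = True
            break
        i = rng.integers(ys.size)
        cy, cx = float(ys[i]), float(xs[i])
        ry = rng.uniform(*spec.blob_radius)
        rx = rng.uniform(*spec.blob_radius)
        y0, y1 = max(int(cy - ry) - 1, 0), min(int(cy + ry) + 2, spec.height)
        x0, x1 = max(int(cx - rx) - 1, 0), min(int(cx + rx) + 2, spec.width)
        local = _ellipse_mask(y1 - y0, x1 - x0, cy - y0, cx - x0, ry, rx)
        local &= tissue[y0:y1, x0:x1] & ~reaction[y0:y1, x0:x1]
        new = int(local.sum())
        if new == 0:
            continue
        if count + new <= target_px:
            reaction[y0:y1, x0:x1] |= local
            count += new
        else:
            ly, lx = np.nonzero(local)
            pick = rng.permutation(ly.size)[: target_px - count]
            reaction[y0 + ly[pick], x0 + lx[pick]] = True
            count = target_px
    return reaction


def generate_field(spec: FieldSpec) -> FieldSample:
    """Render one synthetic field; deterministic for a given spec seed.

    The realized true area fraction matches the target to within pixel
    rounding (well inside ±1 percentage point at any practical raster).
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec, rng)
    reaction = _place_reaction(spec, tissue, rng)
    labels = np.full((spec.height, spec.width), 3, dtype=np.uint8)
    labels[tissue] = 2
    labels[reaction] = 1

    img = np.zeros((spec.height, spec.width, 3), dtype=float)
    for cls, role in ((1, "reaction"), (2, "tissue"), (3, "background")):
        img[labels == cls] = spec.color(role)
    if spec.illumination_amplitude > 0:
        gx = np.linspace(-1.0, 1.0, spec.width)[None, :]
        gy = np.linspace(-1.0, 1.0, spec.height)[:, None]
        gradient = 1.0 + spec.illumination_amplitude * (0.6 * gx + 0.4 * gy)
        img *= gradient[..., None]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = RGBImage(np.clip(np.rint(img), 0, 255).astype(np.uint8))

    c1 = int((labels == 1).sum())
    c2 = int((labels == 2).sum())
    true_af = 100.0 * c1 / (c1 + c2)
    return FieldSample(image=image, labels=labels, true_area_fraction_percent=true_af, spec=spec)


def generate_slide_fields(spec: FieldSpec, n_fields: int = 10) -> list[FieldSample]:
    """Generate ``n_fields`` fields of one slide from independent child seeds."""
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_fields)
    return [
        generate_field(replace(spec, seed=int(child.generate_state(1)[0])))
        for child in children
    ]


# ---------------------------------------------------------------------------
# cohorts

#: Column dictionary of a generated cohort table.
COHORT_COLUMNS = (
    "patient_id",
    "age_yrs",
    "sex",
    "grade",
    "tnm_stage",
    "mucinous",
    "macro_type",
    "localization",
    "hemoglobin_g_dl",
    "wbc_1e9_l",
    "thrombocytes_g_l",
    "glucose_mg_dl",
    "survival_months",
    "event",
    "pas_tumor_filter_hsv",
    "pas_tumor_smart_seg",
    "pas_control_filter_hsv",
    "pas_control_smart_seg",
    "ab_tumor_filter_hsv",
    "ab_tumor_smart_seg",
    "ab_control_filter_hsv",
    "ab_control_smart_seg",
    "pas_tumor_irs",
    "pas_control_irs",
    "ab_tumor_irs",
    "ab_control_irs",
)


@dataclass(frozen=True)
class CohortSpec:
    """Effect structure of a synthetic patient cohort.

    Group means/SDs default to the scale of published colorectal series
    (control ≈ 55–62%, tumor ≈ 10–18%); they are anchors, not claims.
    ``null()`` builds a spec with no built-in effects for calibration runs.
    """

    n_patients: int = 33
    n_mucinous: int = 10
    seed: int = 0
    control_mean_pas: float = 61.6
    control_sd_pas: float = 15.9
    control_mean_ab: float = 55.8
    control_sd_ab: float = 13.5
    tumor_mean_pas: float = 18.4
    tumor_sd_pas: float = 11.3
    tumor_mean_ab: float = 10.1
    tumor_sd_ab: float = 8.3
    backend_disagreement_sd: float = 2.0
    mucinous_ab_shift: float = 7.0
    flat_pas_shift: float = 9.0
    control_pas_ab_rho: float = 0.55
    control_ab_hemoglobin_rho: float = 0.42
    control_pas_glucose_rho: float = 0.40
    survival_scale_months: float = 60.0
    hazard_ratio_high: float = 1.0
    censoring_rate: float = 0.3
    flat_prob: float = 0.39
    proximal_prob: float = 0.30
    male_prob: float = 0.79

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.n_mucinous <= self.n_patients:
            raise ValueError("n_mucinous must lie in [0, n_patients]")
        for name in ("control_sd_pas", "control_sd_ab", "tumor_sd_pas", "tumor_sd_ab",
                     "backend_disagreement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("censoring_rate", "flat_prob", "proximal_prob", "male_prob"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.hazard_ratio_high <= 0:
            raise ValueError("hazard_ratio_high must be > 0")
        for name in ("control_pas_ab_rho", "control_ab_hemoglobin_rho",
                     "control_pas_glucose_rho"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """Spec with every built-in effect removed (for type-I calibration)."""
        c_mean_pas = overrides.get("control_mean_pas", cls.control_mean_pas)
        c_sd_pas = overrides.get("control_sd_pas", cls.control_sd_pas)
        c_mean_ab = overrides.get("control_mean_ab", cls.control_mean_ab)
        c_sd_ab = overrides.get("control_sd_ab", cls.control_sd_ab)
        base = dict(
            tumor_mean_pas=c_mean_pas,
            tumor_sd_pas=c_sd_pas,
            tumor_mean_ab=c_mean_ab,
            tumor_sd_ab=c_sd_ab,
            mucinous_ab_shift=0.0,
            flat_pas_shift=0.0,
            control_pas_ab_rho=0.0,
            control_ab_hemoglobin_rho=0.0,
            control_pas_glucose_rho=0.0,
            hazard_ratio_high=1.0,
        )
        base.update(overrides)
        return cls(**base)


_GRADES = np.array(["in_situ", "G1", "G2", "G3"])
_GRADE_P = np.array([0.03, 0.03, 0.67, 0.27])
_STAGES = np.array(["0", "I", "II", "III", "IV"])
_STAGE_P = np.array([0.03, 0.09, 0.36, 0.40, 0.12])


def _latent_control(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Correlated standard normals: (pas, ab, hemoglobin, glucose) latents."""
    r_ab = spec.control_pas_ab_rho
    r_hb = spec.control_ab_hemoglobin_rho
    r_gl = spec.control_pas_glucose_rho
    corr = np.array(
        [
            [1.0, r_ab, 0.0, r_gl],
            [r_ab, 1.0, r_hb, 0.0],
            [0.0, r_hb, 1.0, 0.0],
            [r_gl, 0.0, 0.0, 1.0],
        ]
    )
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation knobs do not form a valid covariance") from exc
    return rng.standard_normal((n, 4)) @ chol.T


def _irs_from_fraction(a_percent: np.ndarray) -> np.ndarray:
    """Proxy IRS: PP from the area fraction, SI graded by reaction strength."""
    pp = np.array([pp_category(min(max(a / 100.0, 0.0), 1.0)) for a in a_percent])
    si = 1 + (a_percent > 15.0).astype(int) + (a_percent > 40.0).astype(int)
    si[a_percent == 0.0] = 0
    return pp * si


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a synthetic patient cohort table; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    mucinous = (rng.permutation(n) < spec.n_mucinous).astype(int)
    macro = np.where(rng.random(n) < spec.flat_prob, "flat", "protruded")
    localization = np.where(rng.random(n) < spec.proximal_prob, "proximal", "distal")
    sex = np.where(rng.random(n) < spec.male_prob, "male", "female")
    age = np.clip(np.rint(rng.normal(67, 11, n)), 32, 89).astype(int)
    grade = rng.choice(_GRADES, size=n, p=_GRADE_P)
    stage = rng.choice(_STAGES, size=n, p=_STAGE_P)

    latent = _latent_control(spec, rng, n)
    control_pas = np.clip(spec.control_mean_pas + spec.control_sd_pas * latent[:, 0], 0, 100)
    control_ab = np.clip(spec.control_mean_ab + spec.control_sd_ab * latent[:, 1], 0, 100)
    hemoglobin = 13.5 + 1.8 * latent[:, 2]
    glucose = 95.0 + 12.0 * latent[:, 3]
    wbc = np.clip(rng.normal(7.5, 2.0, n), 2.0, None)
    thrombocytes = np.clip(rng.normal(280, 70, n), 80, None)

    z_pas = rng.standard_normal(n)
    z_ab = rng.standard_normal(n)
    tumor_pas = np.clip(
        spec.tumor_mean_pas
        + spec.tumor_sd_pas * z_pas
        + spec.flat_pas_shift * (macro == "flat"),
        0,
        100,
    )
    tumor_ab = np.clip(
        spec.tumor_mean_ab + spec.tumor_sd_ab * z_ab + spec.mucinous_ab_shift * mucinous,
        0,
        100,
    )

    def backend_pair(base: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        smart = base
        hsv = np.clip(base + rng.normal(0, spec.backend_disagreement_sd, n), 0, 100)
        return hsv, smart

    pas_t_hsv, pas_t_smart = backend_pair(tumor_pas)
    pas_c_hsv, pas_c_smart = backend_pair(control_pas)
    ab_t_hsv, ab_t_smart = backend_pair(tumor_ab)
    ab_c_hsv, ab_c_smart = backend_pair(control_ab)

    # exponential survival; hazard ratio applies to above-mean tumor PAS expression
    is_high = tumor_pas > tumor_pas.mean()
    base_rate = np.log(2.0) / spec.survival_scale_months
    rate = base_rate * np.where(is_high, spec.hazard_ratio_high, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        censor_scale = spec.survival_scale_months * (1 - spec.censoring_rate) / spec.censoring_rate
        censor_time = rng.exponential(censor_scale, n)
    else:
        censor_time = np.full(n, np.inf)
    survival = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "age_yrs": age,
            "sex": sex,
            "grade": grade,
            "tnm_stage": stage,
            "mucinous": mucinous,
            "macro_type": macro,
            "localization": localization,
            "hemoglobin_g_dl": np.round(hemoglobin, 1),
            "wbc_1e9_l": np.round(wbc, 1),
            "thrombocytes_g_l": np.round(thrombocytes, 0),
            "glucose_mg_dl": np.round(glucose, 1),
            "survival_months": np.round(survival, 1),
            "event": event,
            "pas_tumor_filter_hsv": pas_t_hsv,
            "pas_tumor_smart_seg": pas_t_smart,
            "pas_control_filter_hsv": pas_c_hsv,
            "pas_control_smart_seg": pas_c_smart,
            "ab_tumor_filter_hsv": ab_t_hsv,
            "ab_tumor_smart_seg": ab_t_smart,
            "ab_control_filter_hsv": ab_c_hsv,
            "ab_control_smart_seg": ab_c_smart,
            "pas_tumor_irs": _irs_from_fraction(pas_t_smart),
            "pas_control_irs": _irs_from_fraction(pas_c_smart),
            "ab_tumor_irs": _irs_from_fraction(ab_t_smart),
            "ab_control_irs": _irs_from_fraction(ab_c_smart),
        },
        columns=list(COHORT_COLUMNS),
    )
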