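"""Field-to-slide aggregation and the semi-quantitative IRS score.

The immunoreactive score is the product of two operator-judged categories:
PP (percentage of positive cells, 0–4) and SI (staining intensity, 0–3),
giving a 0–12 scale banded as negative (0), low (1–2), moderate (3–4) and
strong (6–12).
"""
from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .filter_hsv import FieldResult

logger = logging.getLogger(__name__)

__all__ = [
    "SlideResult",
    "SlideConsistencyError",
    "aggregate_slide",
    "slide_results_frame",
    "IRSInputs",
    "IRSScore",
    "pp_category",
    "irs_score",
    "REACHABLE_IRS_SCORES",
]

#: All products of PP ∈ {0..4} and SI ∈ {0..3}; 5, 7, 10, 11 are unreachable.
REACHABLE_IRS_SCORES = frozenset(p * s for p in range(5) for s in range(4))


class SlideConsistencyError(ValueError):
    """Raised when one slide mixes backends or stains."""


@dataclass(frozen=True)
class SlideResult:
    slide_id: str
    group: str
    stain: str
    backend: str
    field_fractions: tuple[float, ...]
    mean_a_percent: float
    sd_a_percent: float
    median_a_percent: float
    n_fields: int


def aggregate_slide(
    field_results: Sequence[FieldResult],
    slide_id: str,
    group: str = "",
    expected_fields: int = 10,
) -> SlideResult:
    """Summarize per-field area fractions of one slide (mean, sample SD, median).

    All fields must come from the same backend and stain. A warning is
    logged when fewer than ``expected_fields`` fields are supplied; with a
    single field the SD is undefined and reported as 0 (also warned).
    """
    if not field_results:
        raise ValueError(f"slide {slide_id}: no field results")
    backends = {r.backend for r in field_results}
    stains = {r.stain for r in field_results}
    if len(backends) > 1 or len(stains) > 1:
        raise SlideConsistencyError(
            f"slide {slide_id}: mixed backends {sorted(backends)} or stains {sorted(stains)}"
        )
    fractions = tuple(r.area_fraction_percent for r in field_results)
    n = len(fractions)
    if n < expected_fields:
        logger.warning(
            "slide %s: only %d of %d expected fields", slide_id, n, expected_fields
        )
    if n == 1:
        logger.warning("slide %s: single field, SD undefined, reporting 0", slide_id)
        sd = 0.0
    else:
        sd = statistics.stdev(fractions)
    return SlideResult(
        slide_id=slide_id,
        group=group,
        stain=stains.pop(),
        backend=backends.pop(),
        field_fractions=fractions,
        mean_a_percent=statistics.fmean(fractions),
        sd_a_percent=sd,
        median_a_percent=statistics.median(fractions),
        n_fields=n,
    )


def slide_results_frame(slides: Iterable[SlideResult]) -> pd.DataFrame:
    """Tabulate slide results for CSV export."""
    return pd.DataFrame(
        [
            {
                "slide_id": s.slide_id,
                "group": s.group,
                "stain": s.stain,
                "backend": s.backend,
                "n_fields": s.n_fields,
                "mean_a_percent": s.mean_a_percent,
                "sd_a_percent": s.sd_a_percent,
                "median_a_percent": s.median_a_percent,
            }
            for s in slides
        ]
    )


@dataclass(frozen=True)
class IRSInputs:
    """Operator-judged category pair: PP in 0–4, SI in 0–3."""

    pp_category: int
    si: int

    def __post_init__(self) -> None:
        if not 0 <= self.pp_category <= 4:
            raise ValueError("pp_category must lie in 0..4")
        if not 0 <= self.si <= 3:
            raise ValueError("si must lie in 0..3")


@dataclass(frozen=True)
class IRSScore:
    score: int
    band: str


def pp_category(fraction_positive: float) -> int:
    """Categorize the fraction of positively stained cells into PP 0–4.

    Bins (half-open per the classical convention): 0 → 0; (0, 0.10) → 1;
    [0.10, 0.50] → 2; (0.50, 0.80] → 3; (0.80, 1] → 4.
    """
    f = float(fraction_positive)
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction_positive must lie in [0, 1]")
    if f == 0.0:
        return 0
    if f < 0.10:
        return 1
    if f <= 0.50:
        return 2
    if f <= 0.80:
        return 3
    return 4


def irs_score(inputs: IRSInputs) -> IRSScore:
    """Composite IRS = PP × SI with its qualitative band."""
    score = inputs.pp_category * inputs.si
    if score == 0:
        band = "negative"
    elif score <= 2:
        band = "low"
    elif score <= 4:
        band = "moderate"
    else:
        band = "strong"
    return IRSScore(score=score, band=band)
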