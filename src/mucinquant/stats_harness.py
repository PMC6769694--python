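"""Nonparametric statistics for method agreement and cohort comparisons.

Implements Cronbach's alpha, Spearman correlation, paired Wilcoxon
signed-rank, Mann–Whitney U, above/below-mean grouping, Kaplan–Meier /
log-rank survival comparison, and a report generator that assembles the
per-cohort comparison tables.

Exact p-values are computed by full enumeration at small n (Spearman
n ≤ 8, Wilcoxon n ≤ 15, Mann–Whitney n_a + n_b ≤ 12) and by standard
normal/t approximations otherwise. All p-values are two-sided.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateDataError",
    "cronbach_alpha",
    "spearman_rho",
    "wilcoxon_paired",
    "mann_whitney",
    "MeanSplit",
    "split_by_mean",
    "km_curve",
    "km_logrank",
    "LogrankResult",
    "CohortReport",
    "cohort_report",
    "A_PERCENT_COLUMNS",
    "STAINS",
    "BACKENDS",
]

STAINS = ("pas", "ab")
BACKENDS = ("filter_hsv", "smart_seg")
GROUPS = ("tumor", "control")

#: Expected A% columns of a cohort table: ``{stain}_{group}_{backend}``.
A_PERCENT_COLUMNS = tuple(
    f"{stain}_{grp}_{backend}" for stain in STAINS for grp in GROUPS for backend in BACKENDS
)

_COVARIATES = (
    "age_yrs",
    "hemoglobin_g_dl",
    "wbc_1e9_l",
    "thrombocytes_g_l",
    "glucose_mg_dl",
)


class DegenerateDataError(ValueError):
    """Raised when an estimator is undefined on the supplied data."""


# ---------------------------------------------------------------------------
# agreement


def cronbach_alpha(matrix) -> float:
    """Internal-consistency coefficient across method columns.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample (ddof=1) variances. Rows are slides/subjects, columns are
    methods; requires >= 3 rows, >= 2 columns and no missing cells.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("ratings matrix must be 2-D with >= 3 rows and >= 2 columns")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must have no missing cells")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total score variance is zero; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


# ---------------------------------------------------------------------------
# rank-based tests


def _midranks(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, method="average")


def spearman_rho(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks are used for ties. The p-value comes from full enumeration of
    rank permutations when n <= 8 (or ``exact=True``), otherwise from the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input; correlation undefined")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact is None:
        exact = n <= 8
    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs(float(rx_c @ ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = abs(float(rx_c @ ry_c[list(perm)]))
            if stat >= obs - 1e-12 * denom:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * _sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = _midranks(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def wilcoxon_paired(x, y, exact: bool | None = None) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on x − y.

    Zero differences are dropped; tied absolute differences get midranks.
    The statistic is W+ (sum of ranks of positive differences). Exact
    two-sided p by enumerating all 2^n sign assignments when n <= 15,
    otherwise normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise ValueError("need >= 5 non-zero differences")
    w_plus, ranks = _signed_rank_stat(d)
    center = ranks.sum() / 2.0  # null mean of W+
    if exact is None:
        exact = n <= 15
    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        obs = abs(w_plus - center)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(sum(r for s, r in zip(signs, ranks) if s))
            if abs(w - center) >= obs - 1e-12:
                count += 1
        p = count / 2**n
    else:
        sd = math.sqrt(float((ranks**2).sum()) / 4.0)
        z = max(abs(w_plus - center) - 0.5, 0.0) / sd
        p = 2.0 * _sps.norm.sf(z)
    return w_plus, float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    n_a = a.size
    ranks = _midranks(np.concatenate([a, b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, exact: bool | None = None) -> tuple[float, float]:
    """Mann–Whitney U test (two independent samples, midranks for ties).

    Returns U for the first sample. Exact two-sided p by enumerating all
    group assignments when n_a + n_b <= 12, otherwise tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 observations")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0
    if exact is None:
        exact = n <= 12
    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to n <= 16")
        pooled = np.concatenate([a, b])
        ranks = _midranks(pooled)
        obs = abs(u - mu)
        offset = n_a * (n_a + 1) / 2.0
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n_a):
            u_perm = float(ranks[list(combo)].sum() - offset)
            if abs(u_perm - mu) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise DegenerateDataError("all pooled values tied; U variance is zero")
        z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)
        p = 2.0 * _sps.norm.sf(z)
    return u, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# grouping and survival


@dataclass(frozen=True)
class MeanSplit:
    """Above/below-mean partition; values equal to the mean go low."""

    mean: float
    low: np.ndarray
    high: np.ndarray
    is_high: np.ndarray

    @property
    def n_low(self) -> int:
        return int(self.low.size)

    @property
    def n_high(self) -> int:
        return int(self.high.size)


def split_by_mean(values) -> MeanSplit:
    """Partition values into <= mean (low) and > mean (high) groups."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need >= 2 values")
    mean = float(v.mean())
    is_high = v > mean
    if not is_high.any():
        logger.warning("split_by_mean: all values equal the mean; high group is empty")
    return MeanSplit(mean=mean, low=v[~is_high], high=v[is_high], is_high=is_high)


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan–Meier) survival estimate, right-censoring honored.

    Returns one row per distinct event time with columns
    ``time, n_at_risk, n_events, survival``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise ValueError("times and events must be equal-length non-empty 1-D")
    if t.min() < 0:
        raise ValueError("survival times must be >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event flags must be binary")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    for ut in np.unique(t[e == 1]):
        at_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(ut), "n_at_risk": at_risk, "n_events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    curves: Mapping[str, pd.DataFrame]
    group_sizes: Mapping[str, int]


def km_logrank(times, events, groups) -> LogrankResult:
    """Two-group log-rank test with per-group Kaplan–Meier curves."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    g = np.asarray(groups)
    if not (t.shape == e.shape == g.shape) or t.ndim != 1:
        raise ValueError("times, events and groups must be equal-length 1-D")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    for lab in labels:
        if (g == lab).sum() == 0:
            raise ValueError(f"group {lab!r} has zero subjects")
    in_1 = g == labels[0]
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n1 = int((at_risk & in_1).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d1 = int(((t == ut) & (e == 1) & in_1).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (observed - expected) ** 2 / variance
        p = float(_sps.chi2.sf(chi2, df=1))
    curves = {str(lab): km_curve(t[g == lab], e[g == lab]) for lab in labels}
    sizes = {str(lab): int((g == lab).sum()) for lab in labels}
    return LogrankResult(chi_square=float(chi2), p_value=p, curves=curves, group_sizes=sizes)


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class CohortReport:
    """Named comparison tables plus a log of skipped analyses."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    skips: list[str] = field(default_factory=list)

    def skip(self, message: str) -> None:
        logger.warning("cohort report: skipped %s", message)
        self.skips.append(message)


_COMPOSITION_FIELDS = (
    ("sex", "sex"),
    ("gross_morphology", "macro_type"),
    ("localization", "localization"),
    ("histologic_grade", "grade"),
    ("mucin_content", "mucin_content"),
    ("tnm_stage", "tnm_stage"),
)

_SUBGROUP_SPLITS = (
    ("mucinous_vs_nonmucinous", "mucinous", lambda s: s == 1, lambda s: s == 0,
     "mucinous", "nonmucinous"),
    ("flat_vs_protruded", "macro_type", lambda s: s == "flat", lambda s: s == "protruded",
     "flat", "protruded"),
    ("proximal_vs_distal", "localization", lambda s: s == "proximal", lambda s: s == "distal",
     "proximal", "distal"),
    ("grade_g3_vs_g2", "grade", lambda s: s == "G3", lambda s: s == "G2", "G3", "G2"),
    ("stage_iii_vs_ii", "tnm_stage", lambda s: s == "III", lambda s: s == "II", "III", "II"),
)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
    }


def _composition_table(cohort: pd.DataFrame) -> pd.DataFrame:
    n = len(cohort)
    rows = []
    work = cohort.copy()
    if "mucinous" in work.columns:
        work["mucin_content"] = np.where(work["mucinous"] == 1, "mucinous", "nonmucinous")
    for characteristic, col in _COMPOSITION_FIELDS:
        if col not in work.columns:
            continue
        counts = work[col].value_counts()
        for category in sorted(counts.index.astype(str)):
            c = int(counts[category])
            rows.append(
                {
                    "characteristic": characteristic,
                    "category": category,
                    "n": c,
                    "percent": int(round(100.0 * c / n)),
                }
            )
    return pd.DataFrame(rows, columns=["characteristic", "category", "n", "percent"])


def cohort_report(cohort: pd.DataFrame) -> CohortReport:
    """Assemble the standard comparison tables for one cohort.

    Produces, where the required columns are present: a cohort-composition
    summary, paired tumor-vs-control tests, unpaired subgroup comparisons,
    Spearman correlations with clinical covariates, inter-method agreement
    (Cronbach's alpha), and mean-split Kaplan–Meier / log-rank results.
    Analyses whose preconditions fail are skipped with a logged reason.
    """
    if cohort is None or len(cohort) == 0:
        raise ValueError("cohort table is empty")
    report = CohortReport()
    report.tables["composition"] = _composition_table(cohort)

    a_cols = [c for c in A_PERCENT_COLUMNS if c in cohort.columns]

    # --- tumor vs control (paired Wilcoxon) --------------------------------
    rows = []
    for stain in STAINS:
        for backend in BACKENDS:
            t_col, c_col = f"{stain}_tumor_{backend}", f"{stain}_control_{backend}"
            if t_col not in cohort.columns or c_col not in cohort.columns:
                report.skip(f"tumor_vs_control {stain}/{backend}: columns missing")
                continue
            sub = cohort[[t_col, c_col]].dropna()
            try:
                w, p = wilcoxon_paired(sub[t_col].to_numpy(), sub[c_col].to_numpy())
            except (ValueError, DegenerateDataError) as exc:
                report.skip(f"tumor_vs_control {stain}/{backend}: {exc}")
                continue
            row = {"stain": stain, "backend": backend}
            for grp, col in (("tumor", t_col), ("control", c_col)):
                for k, v in _summary(sub[col].to_numpy()).items():
                    row[f"{grp}_{k}"] = v
            row.update(statistic=w, p_value=p)
            rows.append(row)
    if rows:
        report.tables["tumor_vs_control"] = pd.DataFrame(rows)

    # --- subgroup comparisons (Mann-Whitney on tumor A%) -------------------
    rows = []
    for split_name, col, sel_a, sel_b, name_a, name_b in _SUBGROUP_SPLITS:
        if col not in cohort.columns:
            report.skip(f"{split_name}: column {col!r} missing")
            continue
        mask_a = cohort[col].map(sel_a).fillna(False).astype(bool)
        mask_b = cohort[col].map(sel_b).fillna(False).astype(bool)
        for stain in STAINS:
            for backend in BACKENDS:
                v_col = f"{stain}_tumor_{backend}"
                if v_col not in cohort.columns:
                    continue
                a = cohort.loc[mask_a, v_col].dropna().to_numpy()
                b = cohort.loc[mask_b, v_col].dropna().to_numpy()
                try:
                    u, p = mann_whitney(a, b)
                except (ValueError, DegenerateDataError) as exc:
                    report.skip(f"{split_name} {stain}/{backend}: {exc}")
                    continue
                row = {"comparison": split_name, "stain": stain, "backend": backend}
                for name, vals in ((name_a, a), (name_b, b)):
                    for k, v in _summary(vals).items():
                        row[f"{name}_{k}"] = v
                row.update(statistic=u, p_value=p)
                rows.append(row)
    if rows:
        report.tables["subgroups"] = pd.DataFrame(rows)

    # --- covariate correlations (Spearman) ---------------------------------
    rows = []
    for stain in STAINS:
        for grp in GROUPS:
            for backend in BACKENDS:
                v_col = f"{stain}_{grp}_{backend}"
                if v_col not in cohort.columns:
                    continue
                for cov in _COVARIATES:
                    if cov not in cohort.columns:
                        report.skip(f"correlation {v_col} vs {cov}: covariate missing")
                        continue
                    sub = cohort[[v_col, cov]].dropna()
                    try:
                        rho, p = spearman_rho(sub[v_col].to_numpy(), sub[cov].to_numpy())
                    except (ValueError, DegenerateDataError) as exc:
                        report.skip(f"correlation {v_col} vs {cov}: {exc}")
                        continue
                    rows.append(
                        {
                            "stain": stain,
                            "group": grp,
                            "backend": backend,
                            "covariate": cov,
                            "n": len(sub),
                            "rho": rho,
                            "p_value": p,
                        }
                    )
    if rows:
        report.tables["correlations"] = pd.DataFrame(rows)

    # --- inter-method agreement (Cronbach's alpha) -------------------------
    rows = []
    for stain in STAINS:
        for grp in GROUPS:
            cols2 = [f"{stain}_{grp}_{b}" for b in BACKENDS]
            if all(c in cohort.columns for c in cols2):
                try:
                    alpha2 = cronbach_alpha(cohort[cols2].dropna().to_numpy())
                    rows.append(
                        {"stain": stain, "group": grp, "methods": "backends", "alpha": alpha2}
                    )
                except (ValueError, DegenerateDataError) as exc:
                    report.skip(f"agreement {stain}/{grp} backends: {exc}")
            irs_col = f"{stain}_{grp}_irs"
            if irs_col in cohort.columns and all(c in cohort.columns for c in cols2):
                try:
                    alpha3 = cronbach_alpha(cohort[cols2 + [irs_col]].dropna().to_numpy())
                    rows.append(
                        {"stain": stain, "group": grp, "methods": "backends+irs", "alpha": alpha3}
                    )
                except (ValueError, DegenerateDataError) as exc:
                    report.skip(f"agreement {stain}/{grp} backends+irs: {exc}")
    if rows:
        report.tables["agreement"] = pd.DataFrame(rows)

    # --- survival on mean-split expression groups --------------------------
    if {"survival_months", "event"} <= set(cohort.columns):
        km_rows = []
        curve_rows = []
        for stain in STAINS:
            for backend in BACKENDS:
                v_col = f"{stain}_tumor_{backend}"
                if v_col not in cohort.columns:
                    continue
                sub = cohort[[v_col, "survival_months", "event"]].dropna()
                if len(sub) < 4:
                    report.skip(f"km {stain}/{backend}: too few subjects")
                    continue
                split = split_by_mean(sub[v_col].to_numpy())
                if split.n_high == 0 or split.n_low == 0:
                    report.skip(f"km {stain}/{backend}: degenerate mean split")
                    continue
                groups = np.where(split.is_high, "high", "low")
                res = km_logrank(
                    sub["survival_months"].to_numpy(), sub["event"].to_numpy(), groups
                )
                km_rows.append(
                    {
                        "stain": stain,
                        "backend": backend,
                        "n_low": res.group_sizes["low"],
                        "n_high": res.group_sizes["high"],
                        "chi_square": res.chi_square,
                        "p_value": res.p_value,
                    }
                )
                for grp_name, curve in res.curves.items():
                    for _, r in curve.iterrows():
                        curve_rows.append(
                            {"stain": stain, "backend": backend, "expression": grp_name, **r}
                        )
        if km_rows:
            report.tables["km_logrank"] = pd.DataFrame(km_rows)
        if curve_rows:
            report.tables["km_curves"] = pd.DataFrame(curve_rows)
    else:
        report.skip("km: survival columns missing")

    if not a_cols:
        report.skip("no A% columns found; comparative tables limited to composition")
    return report
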