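"""Unit and oracle tests for the statistics harness.

Each exact-p branch is checked against an independent brute-force
enumeration implemented here, in addition to frozen fixture values.
"""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from mucinquant.stats_harness import (
    DegenerateDataError,
    cohort_report,
    cronbach_alpha,
    km_curve,
    km_logrank,
    mann_whitney,
    spearman_rho,
    split_by_mean,
    wilcoxon_paired,
)
from mucinquant.synthetic_data import CohortSpec, generate_cohort

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)


def brute_alpha(matrix):
    """Alpha via the covariance-matrix route: k/(k-1) * (1 - tr C / sum C)."""
    m = np.asarray(matrix, dtype=float)
    cov = np.cov(m, rowvar=False, ddof=1)
    k = m.shape[1]
    return k / (k - 1) * (1.0 - np.trace(cov) / cov.sum())


def brute_spearman(x, y):
    rx, ry = rankdata(x), rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    obs = abs(rxc @ ryc)
    hits = total = 0
    for perm in itertools.permutations(range(len(x))):
        total += 1
        if abs(rxc @ ryc[list(perm)]) >= obs - 1e-12:
            hits += 1
    return rho, hits / total


def brute_wilcoxon(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    center = ranks.sum() / 2.0
    obs = abs(w_plus - center)
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - center) >= obs - 1e-12:
            hits += 1
    return w_plus, hits / 2 ** len(d)


def brute_mann_whitney(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a = len(a)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    offset = n_a * (n_a + 1) / 2.0
    u = ranks[:n_a].sum() - offset
    mu = n_a * len(b) / 2.0
    obs = abs(u - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - offset - mu) >= obs - 1e-12:
            hits += 1
    return u, hits / total


# ---------------------------------------------------------------------------


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        assert cronbach_alpha(np.column_stack([col, col, col])) == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        # analytic construction: orthogonal equal-variance columns
        m = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        assert cronbach_alpha(m) == pytest.approx(0.0)

    def test_fixture_matches_brute_force(self):
        m = np.array([[2, 4, 3], [4, 5, 5], [6, 7, 6], [8, 9, 9], [10, 12, 11]], float)
        alpha = cronbach_alpha(m)
        assert alpha == pytest.approx(brute_alpha(m))
        assert alpha == pytest.approx(0.9955898566703417)  # frozen from the oracle

    def test_zero_total_variance_errors(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(m)

    def test_shape_preconditions(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 3)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 1)))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 100_000))
    def test_duplicating_best_item_never_decreases_alpha(self, seed):
        # monotonicity holds for the item with the highest item-total
        # covariance; it is NOT true for arbitrary columns (see below)
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(6, 3)) * rng.uniform(0.1, 5, size=3) + rng.normal(size=(6, 1))
        cov = np.cov(m, rowvar=False, ddof=1)
        best = int(np.argmax(cov.sum(axis=0)))
        base = cronbach_alpha(m)
        widened = cronbach_alpha(np.column_stack([m, m[:, best]]))
        assert widened >= base - 1e-9

    def test_duplicating_a_poor_item_can_decrease_alpha(self):
        # counterexample to unrestricted duplication monotonicity: the
        # duplicated column is nearly orthogonal to the item total
        rng = np.random.default_rng(1884)
        m = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        base = cronbach_alpha(m)
        widened = cronbach_alpha(np.column_stack([m, m[:, 0]]))
        assert base == pytest.approx(brute_alpha(m))
        assert widened < base  # 0.442 < 0.480


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [2, 4, 8, 16, 32])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_enumeration(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0]
        rho, p = spearman_rho(x, y)
        o_rho, o_p = brute_spearman(x, y)
        assert rho == pytest.approx(o_rho)
        assert p == pytest.approx(o_p)
        assert rho == pytest.approx(0.8818181818181818)  # frozen from the oracle
        assert p == pytest.approx(464 / 40320)

    def test_constant_input_errors(self):
        with pytest.raises(DegenerateDataError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman_rho(x, y)
        from scipy.stats import spearmanr

        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestWilcoxon:
    def test_uniform_shift_gives_extreme_statistic(self):
        tumor = np.arange(1.0, 9.0)
        control = tumor + 3.0
        w, _ = wilcoxon_paired(tumor, control)
        assert w == 0.0  # no positive differences

    def test_n6_fixture_matches_enumeration(self):
        tumor = [12.0, 9.5, 14.0, 11.0, 16.0, 10.0]
        control = [10.0, 11.0, 12.5, 11.5, 12.0, 13.0]
        w, p = wilcoxon_paired(tumor, control)
        o_w, o_p = brute_wilcoxon(tumor, control)
        assert w == pytest.approx(o_w)
        assert p == pytest.approx(o_p)
        assert w == pytest.approx(12.5)  # frozen from the oracle
        assert p == pytest.approx(48 / 64)

    def test_identical_pairs_degenerate(self):
        v = np.arange(6.0)
        with pytest.raises(DegenerateDataError):
            wilcoxon_paired(v, v)

    def test_too_few_nonzero_differences(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])

    def test_approx_branch_matches_scipy(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        w, p = wilcoxon_paired(x, y, exact=False)
        ref = scipy_wilcoxon(x, y, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_spec_example_p_point_one(self):
        _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_fixture_matches_enumeration(self):
        a = [3.1, 4.5, 2.2, 5.0, 4.4]
        b = [6.1, 5.5, 7.0, 4.4, 8.2, 6.6]
        u, p = mann_whitney(a, b)
        o_u, o_p = brute_mann_whitney(a, b)
        assert u == pytest.approx(o_u)
        assert p == pytest.approx(o_p)

    def test_identical_multisets_symmetry(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney(a, list(a))
        assert u == pytest.approx(len(a) * len(a) / 2)

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2], [3, 4, 5])

    def test_approx_branch_matches_scipy(self, rng):
        from scipy.stats import mannwhitneyu

        a = rng.normal(size=20)
        b = rng.normal(0.5, size=25)
        u, p = mann_whitney(a, b, exact=False)
        ref = mannwhitneyu(a, b, method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSplitByMean:
    def test_simple_split(self):
        split = split_by_mean([1.0, 2.0, 3.0, 4.0])
        assert split.low.tolist() == [1.0, 2.0]
        assert split.high.tolist() == [3.0, 4.0]

    def test_all_equal_goes_low_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            split = split_by_mean([5.0, 5.0, 5.0])
        assert split.n_low == 3 and split.n_high == 0
        assert any("high group is empty" in r.message for r in caplog.records)

    def test_generator_cohort_matches_hand_split(self):
        cohort = generate_cohort(CohortSpec(seed=21))
        values = cohort["pas_tumor_filter_hsv"].to_numpy()
        split = split_by_mean(values)
        mean = sum(values) / len(values)  # independent recomputation
        assert split.n_high == int(np.sum(values > mean))
        assert split.n_low == len(values) - split.n_high


class TestKaplanMeier:
    def test_all_events_by_hand(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censoring_honored(self):
        # censoring at t=2 adds no drop, but shrinks the t=3 risk set to one
        curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve["survival"].tolist() == pytest.approx([2 / 3, 0.0])
        assert curve["n_at_risk"].tolist() == [3, 1]

    def test_curve_non_increasing_from_one(self, rng):
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        if events.sum() == 0:
            events[0] = 1
        curve = km_curve(times, events)
        surv = curve["survival"].to_numpy()
        assert (np.diff(surv) <= 1e-12).all()
        assert surv[0] <= 1.0

    def test_identical_groups_chi_square_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        res = km_logrank(times, events, groups)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(20, size=50)
        events = rng.integers(0, 2, size=50)
        groups = np.where(rng.random(50) < 0.5, "a", "b")
        res = km_logrank(times, events, groups)
        mask = groups == "a"
        ref = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
        assert res.p_value == pytest.approx(ref.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])

    def test_binary_events_required(self):
        with pytest.raises(ValueError):
            km_curve([1.0, 2.0], [1, 2])


@pytest.fixture(scope="module")
def report():
    return cohort_report(generate_cohort(CohortSpec(seed=4)))


class TestCohortReport:
    def test_all_tables_present(self, report):
        assert {
            "composition",
            "tumor_vs_control",
            "subgroups",
            "correlations",
            "agreement",
            "km_logrank",
            "km_curves",
        } <= set(report.tables)

    def test_composition_percent_sums(self, report):
        comp = report.tables["composition"]
        mucin = comp[comp["characteristic"] == "mucin_content"]
        assert mucin["n"].sum() == 33

    def test_builtin_shift_detected(self, report):
        tvc = report.tables["tumor_vs_control"]
        assert (tvc["p_value"] < 0.05).all()
        assert (tvc["tumor_mean"] < tvc["control_mean"]).all()

    def test_single_patient_cohort_skips_cleanly(self, caplog):
        cohort = generate_cohort(CohortSpec(n_patients=1, n_mucinous=0, seed=0))
        with caplog.at_level("WARNING"):
            report = cohort_report(cohort)
        assert "composition" in report.tables
        assert "tumor_vs_control" not in report.tables
        assert report.skips  # every comparative table logged a reason

    def test_missing_survival_skips_km_only(self):
        cohort = generate_cohort(CohortSpec(seed=4)).drop(
            columns=["survival_months", "event"]
        )
        report = cohort_report(cohort)
        assert "km_logrank" not in report.tables
        assert "tumor_vs_control" in report.tables
        assert any(s.startswith("km") for s in report.skips)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_report(pd.DataFrame())
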