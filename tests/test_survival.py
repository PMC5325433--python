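"""Survival and categorical statistics: KM, weighted log-rank, Cox, tables."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcmarkers import (
    chi_square_rxc,
    cox_fit,
    fisher_exact_2x2,
    gehan_wilcoxon_test,
    km_estimate,
    mann_whitney_u,
)


# -- Kaplan-Meier -----------------------------------------------------------

def test_km_no_events_flat():
    curve = km_estimate([5, 8, 13], [0, 0, 0])
    assert np.all(curve.survival == 1.0)


def test_km_hand_product_limit():
    curve = km_estimate([1, 2], [1, 1])
    assert curve.survival_at(1) == pytest.approx(0.5)
    assert curve.survival_at(2) == pytest.approx(0.0)


def test_km_equals_one_minus_ecdf_without_censoring(rng):
    times = rng.exponential(100, 40)
    curve = km_estimate(times, np.ones(40, dtype=int))
    for t in np.quantile(times, [0.2, 0.5, 0.9]):
        assert curve.survival_at(t) == pytest.approx(np.mean(times > t))


def test_km_invariants(rng):
    times = rng.exponential(50, 60)
    events = rng.integers(0, 2, 60)
    curve = km_estimate(times, events)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [1, 1])


# -- weighted log-rank / Gehan ----------------------------------------------

def test_gehan_identical_groups_zero():
    t = [3, 5, 8, 12]
    e = [1, 0, 1, 1]
    res = gehan_wilcoxon_test(t + t, e + e, ["a"] * 4 + ["b"] * 4, exact=False)
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == 1.0


def test_gehan_rejects_degenerate_groups():
    with pytest.raises(ValueError):
        gehan_wilcoxon_test([1, 2], [1, 1], ["a", "a"])


def test_gehan_matches_lifelines_wilcoxon(rng):
    """Dual route: authored statistic vs lifelines' Gehan-weighted log-rank."""
    from lifelines.statistics import multivariate_logrank_test

    for _ in range(5):
        n = 40
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        g = rng.integers(0, 3, n)
        if len(np.unique(g)) < 3 or e.sum() == 0:
            continue
        mine = gehan_wilcoxon_test(t, e, g, exact=False)
        ref = multivariate_logrank_test(t, g, e, weightings="wilcoxon")
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-8)


def test_logrank_variant_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    t = rng.exponential(10, 30)
    e = rng.integers(0, 2, 30)
    g = (rng.random(30) < 0.5).astype(int)
    mine = gehan_wilcoxon_test(t, e, g, weights="logrank", exact=False)
    ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-8)


def test_peto_variant_downweights_late_times(rng):
    """Peto-Prentice weights decay with the modified KM estimate, so the
    variant runs, yields a valid p, and generally differs from Gehan."""
    t = rng.exponential(10, 50)
    e = rng.integers(0, 2, 50)
    g = (rng.random(50) < 0.5).astype(int)
    peto = gehan_wilcoxon_test(t, e, g, weights="peto", exact=False)
    gehan = gehan_wilcoxon_test(t, e, g, weights="gehan", exact=False)
    assert 0 <= peto.p_value <= 1
    assert peto.statistic != pytest.approx(gehan.statistic)


def test_gehan_small_sample_chi2_close_to_permutation(rng):
    t = [2, 4, 5, 7, 9, 11, 3, 6, 8, 10]
    e = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0]
    g = ["a"] * 5 + ["b"] * 5
    exact = gehan_wilcoxon_test(t, e, g, exact=True)
    approx = gehan_wilcoxon_test(t, e, g, exact=False)
    assert exact.statistic == pytest.approx(approx.statistic)
    assert abs(exact.p_value - approx.p_value) < 0.12


def test_gehan_power_exceeds_null_rate(rng):
    """Separated hazards must be rejected more often than equal hazards."""
    rejections = {"null": 0, "alt": 0}
    reps = 120
    for i in range(reps):
        r = np.random.default_rng(1000 + i)
        t0 = r.exponential(10, 30)
        t1_null = r.exponential(10, 30)
        t1_alt = r.exponential(3.5, 30)
        e = np.ones(60, dtype=int)
        g = np.r_[np.zeros(30), np.ones(30)]
        for key, t1 in (("null", t1_null), ("alt", t1_alt)):
            res = gehan_wilcoxon_test(np.r_[t0, t1], e, g, exact=False)
            rejections[key] += res.p_value < 0.05
    assert rejections["alt"] > rejections["null"]
    assert rejections["alt"] / reps > 0.8


# -- Cox --------------------------------------------------------------------

def test_cox_null_covariate_recovers_hr_one(rng):
    n = 300
    df = pd.DataFrame(
        {
            "time_days": rng.exponential(100, n),
            "event": np.ones(n, dtype=int),
            "x": rng.normal(size=n),
        }
    )
    res = cox_fit(df, ["x"])
    row = res.table.loc["x"]
    assert row["ci_low"] <= 1.0 <= row["ci_high"]
    assert abs(row["coef"]) < 3 * row["se"]


def test_cox_recovers_log_hazard_ratio(rng):
    n = 400
    x = rng.integers(0, 2, n)
    lam = 0.01 * np.exp(np.log(2) * x)
    df = pd.DataFrame(
        {
            "time_days": rng.exponential(1 / lam),
            "event": np.ones(n, dtype=int),
            "x": x,
        }
    )
    res = cox_fit(df, ["x"])
    row = res.table.loc["x"]
    assert abs(row["coef"] - np.log(2)) < 3 * row["se"]
    assert row["ci_low"] <= row["hr"] <= row["ci_high"]


def test_cox_rescaling_equivariance(rng):
    n = 200
    x = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "time_days": rng.exponential(np.exp(-0.5 * x) * 50),
            "event": np.ones(n, dtype=int),
            "x": x,
        }
    )
    res1 = cox_fit(df, ["x"])
    df10 = df.assign(x=df["x"] * 10)
    res10 = cox_fit(df10, ["x"])
    assert res10.table.loc["x", "coef"] == pytest.approx(
        res1.table.loc["x", "coef"] / 10, rel=1e-4
    )


def test_cox_univariate_fits_each_variable_alone(rng):
    n = 150
    df = pd.DataFrame(
        {
            "time_days": rng.exponential(100, n),
            "event": rng.integers(0, 2, n) | 1,
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        }
    )
    res = cox_fit(df, ["a", "b"], univariate=True)
    assert list(res.table.index) == ["a", "b"]
    alone = cox_fit(df, ["a"])
    assert res.table.loc["a", "coef"] == pytest.approx(alone.table.loc["a", "coef"])


def test_cox_requires_events():
    df = pd.DataFrame({"time_days": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
    with pytest.raises(ValueError):
        cox_fit(df, ["x"])


# -- contingency tables -----------------------------------------------------

def fisher_enumeration_p(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, n = a + b, a + b + c + d
    c1 = a + c
    probs = []
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        probs.append((x, stats.hypergeom.pmf(x, n, r1, c1)))
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize(
    "table", [[[3, 1], [1, 3]], [[10, 2], [3, 9]], [[5, 5], [5, 5]], [[1, 9], [8, 2]]]
)
def test_fisher_matches_enumeration(table):
    res = fisher_exact_2x2(table)
    assert res.p_value == pytest.approx(fisher_enumeration_p(table))


def test_fisher_zero_margin_p_one():
    assert fisher_exact_2x2([[0, 0], [3, 4]]).p_value == 1.0


def test_fisher_doubling_sharpens_evidence():
    base = fisher_exact_2x2([[8, 2], [3, 7]]).p_value
    doubled = fisher_exact_2x2([[16, 4], [6, 14]]).p_value
    assert doubled <= base


def test_fisher_rejects_negatives():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -1], [2, 3]])


def test_chi_square_zero_statistic_on_expected_table():
    res = chi_square_rxc([[10, 20], [10, 20]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_matches_hand_formula_on_stage_counts():
    """2x3 stage distribution (Group 1 vs Group 2) against the summed
    Pearson formula computed cell by cell."""
    table = np.array([[1, 24, 5], [3, 13, 14]], dtype=float)
    res = chi_square_rxc(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    hand = ((table - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(hand)
    assert res.extras["df"] == 2
    assert res.extras["low_expected_flag"]  # expected counts < 5 present
    assert 0 <= res.extras["mc_p_value"] <= 1


def test_chi_square_monte_carlo_converges_to_enumeration():
    """On a tiny 2x2 table the conditional null is fully enumerable: the
    Monte-Carlo exact p must converge to the enumerated probability of a
    chi-square statistic at least as extreme."""
    table = np.array([[3, 1], [2, 6]], dtype=float)
    n, r1, c1 = table.sum(), table[0].sum(), table[:, 0].sum()

    def chi2_of(a):
        t = np.array([[a, r1 - a], [c1 - a, n - r1 - c1 + a]], dtype=float)
        expected = np.outer(t.sum(1), t.sum(0)) / n
        return ((t - expected) ** 2 / expected).sum()

    obs = chi2_of(table[0, 0])
    exact_p = sum(
        stats.hypergeom.pmf(a, n, r1, c1)
        for a in range(int(max(0, r1 + c1 - n)), int(min(r1, c1)) + 1)
        if chi2_of(a) >= obs - 1e-9
    )
    res = chi_square_rxc(table, mc_reps=100_000, seed=7)
    assert res.extras["low_expected_flag"]
    assert res.extras["mc_p_value"] == pytest.approx(exact_p, abs=0.01)
    large = chi_square_rxc([[40, 60], [55, 45]])
    assert not large.extras["low_expected_flag"]


def test_chi_square_rejects_zero_margin():
    with pytest.raises(ValueError):
        chi_square_rxc([[0, 0], [1, 2]])


# -- Mann-Whitney -----------------------------------------------------------

def test_mwu_complete_separation():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / comb(6, 3) * 1)  # only the two extremes


def test_mwu_identical_samples_exact_p_one():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_mwu_normal_approximation_tracks_exact(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 8, 6).astype(float)
    y = rng.integers(0, 8, 6).astype(float)
    exact = mann_whitney_u(x, y)  # n=12 -> enumeration
    approx = mann_whitney_u(x, y, exact_max_n=0)  # force normal approximation
    assert "exact" in exact.method and "approximation" in approx.method
    assert abs(exact.p_value - approx.p_value) < 0.08
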