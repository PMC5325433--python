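"""Survival and categorical statistics for subgroup comparisons.

Time-to-event records are disease-specific survival times (days from surgery
to death from the primary tumor; other deaths and patients alive at last
follow-up are censored).  The module wraps the Kaplan-Meier estimator and
Cox proportional-hazards model (via lifelines, Breslow tie handling), and
implements the weighted log-rank family — in particular the Gehan-Breslow
generalized Wilcoxon test, which weights each event time by the number at
risk and hence emphasizes early differences — together with the Fisher /
chi-square / Mann-Whitney tests used for the clinicopathological tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve with at-risk and event counts."""

    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: dict
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CoxResult:
    """Cox proportional-hazards fit: per-variable HR, 95% CI, Wald p."""

    table: pd.DataFrame  # variable, coef, se, hr, ci_low, ci_high, p
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def _check_times(time: np.ndarray) -> None:
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate; censored times reduce the risk set without steps."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    timeline = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(timeline).to_numpy()
    return KMCurve(
        timeline=timeline,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        n_events=table["observed"].to_numpy(),
    )


def _weighted_logrank_stat(
    time: np.ndarray, event: np.ndarray, group_codes: np.ndarray,
    n_groups: int, weights: str,
) -> float:
    """Chi-square statistic of the k-sample weighted log-rank test."""
    order = np.argsort(time, kind="stable")
    time, event, group_codes = time[order], event[order], group_codes[order]
    event_times = np.unique(time[event == 1])
    z = np.zeros(n_groups)
    V = np.zeros((n_groups, n_groups))
    km_tilde = 1.0  # Peto-Prentice modified survivor estimate, left-continuous
    for t in event_times:
        at_risk = time >= t
        n_i = int(at_risk.sum())
        d_i = int((event[time == t]).sum())
        if n_i == 0 or d_i == 0:
            continue
        n_ij = np.bincount(group_codes[at_risk], minlength=n_groups)
        d_ij = np.bincount(
            group_codes[(time == t) & (event == 1)], minlength=n_groups
        )
        if weights == "gehan":
            w = float(n_i)
        elif weights == "logrank":
            w = 1.0
        elif weights == "peto":
            w = km_tilde
        else:
            raise ValueError(f"unknown weight variant {weights!r}")
        p = n_ij / n_i
        z += w * (d_ij - d_i * p)
        if n_i > 1:
            factor = w * w * d_i * (n_i - d_i) / (n_i - 1)
            V += factor * (np.diag(p) - np.outer(p, p))
        km_tilde *= 1.0 - d_i / (n_i + 1)
    zr, Vr = z[:-1], V[:-1, :-1]
    if np.allclose(zr, 0):
        return 0.0
    return float(zr @ np.linalg.pinv(Vr) @ zr)


def gehan_wilcoxon_test(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
    weights: str = "gehan",
    exact: Optional[bool] = None,
    exact_max_n: int = 12,
) -> TestResult:
    """Weighted log-rank comparison of >= 2 survival curves.

    ``weights``: ``"gehan"`` (number at risk; generalized Wilcoxon, the
    default), ``"peto"`` (Peto-Prentice) or ``"logrank"`` (unweighted).  The
    p-value uses the chi-square approximation with df = groups - 1; for two
    groups with total n <= ``exact_max_n`` an exact permutation p over all
    label assignments is used instead (force with ``exact=True/False``).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _check_times(time)
    labels, codes = np.unique(group, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    counts = np.bincount(codes)
    if (counts == 0).any():
        raise ValueError("every group must be non-empty")
    g = len(labels)
    stat = _weighted_logrank_stat(time, event, codes, g, weights)
    n_total = len(time)
    if exact is None:
        exact = g == 2 and n_total <= exact_max_n
    if exact:
        if g != 2:
            raise ValueError("exact permutation p is implemented for 2 groups")
        n1 = int(counts[0])
        ge = 0
        total = 0
        idx = np.arange(n_total)
        for subset in combinations(idx, n1):
            perm_codes = np.ones(n_total, dtype=int)
            perm_codes[list(subset)] = 0
            s = _weighted_logrank_stat(time, event, perm_codes, g, weights)
            ge += s >= stat - 1e-12
            total += 1
        p = ge / total
        method = f"{weights} log-rank (exact permutation)"
    else:
        p = float(stats.chi2.sf(stat, df=g - 1))
        method = f"{weights} log-rank (chi-square df={g - 1})"
    return TestResult(
        statistic=stat,
        p_value=p,
        method=method,
        n={str(lab): int(c) for lab, c in zip(labels, counts)},
    )


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time_days",
    event_col: str = "event",
    univariate: bool = False,
) -> CoxResult:
    """Cox proportional-hazards regression (Breslow tie handling via lifelines).

    Covariates must be numeric-coded (ordinal three-level variables as
    0/1/2).  ``univariate=True`` fits each covariate in its own model and
    stacks the per-variable rows.  Non-convergence raises a diagnostic
    :class:`lifelines.exceptions.ConvergenceError` rather than returning
    silent output.
    """
    covariates = list(covariates)
    df = records[[duration_col, event_col] + covariates].copy()
    _check_times(df[duration_col].to_numpy(dtype=float))
    if int(df[event_col].sum()) < 1:
        raise ValueError("need at least one event to fit a Cox model")
    variable_sets = [[c] for c in covariates] if univariate else [covariates]
    rows = []
    ll = np.nan
    for vs in variable_sets:
        cph = CoxPHFitter()
        try:
            cph.fit(df[[duration_col, event_col] + vs],
                    duration_col=duration_col, event_col=event_col)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"Cox fit failed for covariates {vs}: {err}"
            ) from err
        summ = cph.summary
        for var in vs:
            rows.append(
                {
                    "variable": var,
                    "coef": float(summ.loc[var, "coef"]),
                    "se": float(summ.loc[var, "se(coef)"]),
                    "hr": float(summ.loc[var, "exp(coef)"]),
                    "ci_low": float(summ.loc[var, "exp(coef) lower 95%"]),
                    "ci_high": float(summ.loc[var, "exp(coef) upper 95%"]),
                    "p": float(summ.loc[var, "p"]),
                }
            )
        ll = float(cph.log_likelihood_)
    table = pd.DataFrame(rows).set_index("variable")
    return CoxResult(
        table=table,
        log_likelihood=ll,
        converged=True,
        n=int(len(df)),
        n_events=int(df[event_col].sum()),
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    p sums the hypergeometric probabilities of tables as or less probable
    than the observed one (conditional on the margins).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]) if t[0, 1] * t[1, 0] else np.inf
    return TestResult(
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        method="fisher exact (two-sided)",
        n={"total": int(t.sum())},
    )


def chi_square_rxc(
    table,
    min_expected: float = 5.0,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Pearson chi-square test of an r x c table, df = (r-1)(c-1).

    When any expected count falls below ``min_expected`` the asymptotic p is
    flagged and a seeded Monte-Carlo exact p (sampling ``mc_reps`` tables with
    the observed margins) is attached in ``extras``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    if np.any(row_m == 0) or np.any(col_m == 0):
        raise ValueError("zero row or column margin")
    stat, p, dof, expected = stats.chi2_contingency(t, correction=False)
    extras: dict = {"df": int(dof), "min_expected": float(expected.min())}
    if expected.min() < min_expected:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(row_m.astype(int), col_m.astype(int))
        samples = dist.rvs(mc_reps, random_state=rng)
        chi2_samples = ((samples - expected) ** 2 / expected).sum(axis=(-2, -1))
        mc_p = (np.count_nonzero(chi2_samples >= stat - 1e-9) + 1) / (mc_reps + 1)
        extras.update(
            {"low_expected_flag": True, "mc_p_value": float(mc_p), "mc_reps": mc_reps}
        )
    else:
        extras["low_expected_flag"] = False
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method=f"pearson chi-square (df={dof})",
        n={"total": int(t.sum())},
        extras=extras,
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For total n <= ``exact_max_n`` the permutation distribution of U is
    enumerated exactly (ties handled through midranks); otherwise the normal
    approximation with tie and continuity corrections (scipy) is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_max_n:
        us = []
        for subset in combinations(range(n1 + n2), n1):
            r1 = ranks[list(subset)].sum()
            us.append(r1 - n1 * (n1 + 1) / 2)
        us = np.asarray(us)
        eps = 1e-9
        p_le = np.count_nonzero(us <= u_obs + eps) / len(us)
        p_ge = np.count_nonzero(us >= u_obs - eps) / len(us)
        p = min(1.0, 2 * min(p_le, p_ge))
        method = "mann-whitney U (exact enumeration)"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "mann-whitney U (normal approximation)"
    return TestResult(
        statistic=u_obs, p_value=p, method=method, n={"x": n1, "y": n2}
    )
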