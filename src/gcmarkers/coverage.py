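"""Marker-panel coverage: how well a set of markers jointly detects cases.

A case is covered by a panel when it is positive for at least one panel
marker ("coupling" of complementary markers).  Calls are boolean with
missing allowed; missing counts as negative for coverage, since an
unevaluable core cannot demonstrate positivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations, product
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .ihc import BAND_NEGATIVE, BandScheme


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    if calls.shape[1] < 1:
        raise ValueError("call table needs at least one marker")
    if calls.index.has_duplicates or calls.columns.has_duplicates:
        raise ValueError("case and marker ids must be unique")
    return calls.astype("boolean")


def calls_from_scores(
    scores: pd.DataFrame,
    positivity_rule: Union[Mapping[str, float], BandScheme],
) -> pd.DataFrame:
    """Binarize a case x marker numeric score table into positive/negative calls.

    ``positivity_rule`` is either a per-marker numeric threshold (positive when
    score >= threshold, mirroring the screen's inclusive tumor floor) or a
    :class:`~gcmarkers.ihc.BandScheme` (positive when the band is not ``-``).
    Missing scores yield missing calls.
    """
    if scores.index.has_duplicates or scores.columns.has_duplicates:
        raise ValueError("case and marker ids must be unique")
    calls = pd.DataFrame(
        index=scores.index, columns=scores.columns, dtype="boolean"
    )
    if isinstance(positivity_rule, BandScheme):
        for marker in scores.columns:
            calls[marker] = scores[marker].map(
                lambda v, m=marker: (
                    pd.NA
                    if pd.isna(v)
                    else positivity_rule.band(m, int(v)) != BAND_NEGATIVE
                )
            ).astype("boolean")
    else:
        unknown = sorted(set(scores.columns) - set(positivity_rule))
        if unknown:
            raise KeyError(f"no positivity threshold for markers {unknown}")
        for marker in scores.columns:
            thr = positivity_rule[marker]
            calls[marker] = (
                scores[marker].ge(thr).mask(scores[marker].isna()).astype("boolean")
            )
    return calls


@dataclass
class PanelCoverageResult:
    """Coverage of a marker panel over a case set.

    ``pattern_counts`` maps each joint positivity pattern — a tuple of
    booleans in panel order — to its case count (missing counted negative).
    """

    panel: tuple
    covered: int
    total: int
    fraction: float
    pattern_counts: dict

    def percent(self, decimals: int = 1) -> float:
        return coverage_percent(self.covered, self.total, decimals)


def coverage(calls: pd.DataFrame, panel: Sequence[str]) -> PanelCoverageResult:
    """Coverage of ``panel``: cases positive for >= 1 panel marker.

    Missing calls are treated as negative.  ``pattern_counts`` enumerates all
    2^|panel| positivity patterns (including never-observed ones at count 0).
    """
    calls = _validate_calls(calls)
    panel = tuple(panel)
    if len(panel) == 0:
        raise ValueError("panel must contain at least one marker")
    missing = [m for m in panel if m not in calls.columns]
    if missing:
        raise KeyError(f"panel markers not in call table: {missing}")
    sub = calls[list(panel)].fillna(False).astype(bool)
    covered = int(sub.any(axis=1).sum())
    total = int(len(sub))
    counts = {pat: 0 for pat in product((True, False), repeat=len(panel))}
    for pat, n in sub.value_counts().items():
        key = tuple(pat) if isinstance(pat, tuple) else (pat,)
        counts[key] = int(n)
    return PanelCoverageResult(
        panel=panel,
        covered=covered,
        total=total,
        fraction=covered / total if total else 0.0,
        pattern_counts=counts,
    )


def coverage_percent(covered: int, total: int, decimals: int = 1) -> float:
    """Percentage covered, rounded half-away-from-zero.

    Matches the printed conventions 50/56 -> 89.3, 98/106 -> 92.5,
    40/56 -> 71.4 and (at 0 decimals) 465/1496 -> 31.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= covered <= total:
        raise ValueError("covered must lie in [0, total]")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(covered) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(pct)


def best_panel_greedy(
    calls: pd.DataFrame, max_size: int
) -> tuple[list, pd.DataFrame]:
    """Greedy set cover: grow a panel marker-by-marker to maximize coverage.

    At each step the marker covering the most still-uncovered cases is added
    (ties broken by marker id order).  Returns the ordered panel and a trace
    with per-step newly covered / cumulative covered counts.  Stops early once
    no marker adds coverage.
    """
    calls = _validate_calls(calls)
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    filled = calls.fillna(False).astype(bool)
    uncovered = pd.Series(True, index=filled.index)
    panel: list = []
    trace_rows = []
    for _ in range(min(max_size, filled.shape[1])):
        gains = {
            m: int((filled[m] & uncovered).sum())
            for m in filled.columns
            if m not in panel
        }
        if not gains:
            break
        best = min(sorted(gains), key=lambda m: -gains[m])
        if gains[best] == 0:
            break
        panel.append(best)
        uncovered &= ~filled[best]
        trace_rows.append(
            {
                "marker": best,
                "newly_covered": gains[best],
                "cumulative_covered": int(len(filled) - uncovered.sum()),
                "total": int(len(filled)),
            }
        )
    trace = pd.DataFrame(
        trace_rows, columns=["marker", "newly_covered", "cumulative_covered", "total"]
    )
    return panel, trace


def exhaustive_best_panel(
    calls: pd.DataFrame, size: int
) -> tuple[tuple, int]:
    """Best panel of exactly ``size`` markers by exhaustive enumeration.

    Intended for small marker sets; returns (panel, covered) with ties broken
    lexicographically.
    """
    calls = _validate_calls(calls)
    filled = calls.fillna(False).astype(bool)
    best: Optional[tuple] = None
    best_cov = -1
    for panel in combinations(sorted(filled.columns), size):
        cov = int(filled[list(panel)].any(axis=1).sum())
        if cov > best_cov:
            best, best_cov = panel, cov
    if best is None:
        raise ValueError(f"fewer than {size} markers available")
    return best, best_cov
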