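"""Semi-quantitative IHC scoring model for tissue-microarray (TMA) cores.

Membranous staining of each marker (CDH17, CLDN18, CLDN7) is scored per core
as the proportion of positive tumor cells on a 0-10 scale (score 0 = 0%,
score s = (10(s-1), 10s]% for s >= 1).  Duplicate cores per site (primary
lesion ``Pr`` or lymph-node metastasis ``LN``) are summed to a 0-20 IHC score.
Marker-specific bands (``++`` strong / ``+`` moderate / ``-`` weak-negative)
partition the 0-20 scale, and the joint CDH17/CLDN18 band of the primary
lesion assigns each case to Group 1, Group 2, Group 3 or leaves it
unclassified.  Whole-section staining is summarized by four stepwise
categories of the 0-10 score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

MARKERS = ("CDH17", "CLDN18", "CLDN7")
SITES = ("Pr", "LN")

BAND_STRONG = "++"
BAND_MODERATE = "+"
BAND_NEGATIVE = "-"
BANDS = (BAND_STRONG, BAND_MODERATE, BAND_NEGATIVE)

GROUP1 = "Group1"
GROUP2 = "Group2"
GROUP3 = "Group3"
UNCLASSIFIED = "unclassified"
GROUPS = (GROUP1, GROUP2, GROUP3, UNCLASSIFIED)


@dataclass(frozen=True)
class BandScheme:
    """Marker-specific band intervals (inclusive) partitioning the 0-20 score.

    ``derived`` flags intervals that are complements of explicitly stated
    ranges rather than stated outright.
    """

    intervals: Mapping[str, Mapping[str, tuple[int, int]]]
    derived: frozenset = frozenset()

    def __post_init__(self) -> None:
        for marker, bands in self.intervals.items():
            if set(bands) != set(BANDS):
                raise ValueError(f"{marker}: bands must be exactly {BANDS}")
            covered = sorted(
                (lo, hi, b) for b, (lo, hi) in bands.items()
            )
            if covered[0][0] != 0 or covered[-1][1] != 20:
                raise ValueError(f"{marker}: band intervals must span 0-20")
            for (lo, hi, b), (lo2, hi2, b2) in zip(covered, covered[1:]):
                if lo > hi or lo2 != hi + 1:
                    raise ValueError(
                        f"{marker}: bands {b} and {b2} leave a gap or overlap"
                    )

    def band(self, marker: str, value: Optional[int]) -> Optional[str]:
        """Band label of an aggregated 0-20 score; ``None`` stays ``None``."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        marker = _canon_marker(marker, self.intervals)
        value = int(value)
        if not 0 <= value <= 20:
            raise ValueError(f"IHC score {value} outside 0-20")
        for b, (lo, hi) in self.intervals[marker].items():
            if lo <= value <= hi:
                return b
        raise AssertionError("validated scheme must cover 0-20")


#: Published intervals for ++/+ plus derived complements for the negative band.
DEFAULT_BANDS = BandScheme(
    intervals={
        "CDH17": {BAND_STRONG: (18, 20), BAND_MODERATE: (9, 17), BAND_NEGATIVE: (0, 8)},
        "CLDN18": {BAND_STRONG: (14, 20), BAND_MODERATE: (6, 13), BAND_NEGATIVE: (0, 5)},
        "CLDN7": {BAND_STRONG: (12, 20), BAND_MODERATE: (8, 11), BAND_NEGATIVE: (0, 7)},
    },
    derived=frozenset({("CLDN18", BAND_NEGATIVE), ("CLDN7", BAND_NEGATIVE)}),
)


def _canon_marker(marker: str, known: Iterable[str]) -> str:
    for m in known:
        if m.lower() == str(marker).strip().lower():
            return m
    raise KeyError(f"unknown marker {marker!r}; known: {sorted(known)}")


def proportion_to_score(pct: float) -> int:
    """Map a membranous-positive percentage (0-100) to the 0-10 core score.

    0% maps to 0; otherwise the score is ceil(pct / 10), so 51-60% -> 6 and a
    fractional 10.5% already falls in the 11-20% bin (score 2).
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct == 0:
        return 0
    return math.ceil(pct / 10)


def _check_core(score: int) -> int:
    score_i = int(score)
    if score_i != score or not 0 <= score_i <= 10:
        raise ValueError(f"core score {score!r} must be an integer in 0-10")
    return score_i


@dataclass(frozen=True)
class IHCScore:
    """Aggregated per-site IHC score: sum of the duplicate 0-10 cores (0-20).

    ``imputed`` marks scores rebuilt from a single core (doubled to keep the
    0-20 scale); ``value`` is ``None`` when no core was evaluable.
    """

    case_id: str
    marker: str
    site: str
    value: Optional[int]
    imputed: bool = False


def aggregate_cores(cores: Sequence[Optional[int]]) -> tuple[Optional[int], bool]:
    """Sum duplicate core scores to the 0-20 site score.

    Returns ``(value, imputed)``: both cores -> plain sum; one core -> doubled
    with ``imputed=True``; none -> ``(None, False)``.
    """
    present = [
        _check_core(c)
        for c in cores
        if c is not None and not (isinstance(c, float) and math.isnan(c))
    ]
    if len(cores) > 2:
        raise ValueError(f"at most 2 replicate cores per site, got {len(cores)}")
    if len(present) == 2:
        return present[0] + present[1], False
    if len(present) == 1:
        return 2 * present[0], True
    return None, False


def aggregate_core_table(cores: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-core table to per-(case, marker, site) IHC scores.

    Expects columns ``case_id, marker, site, replicate, score``; returns
    columns ``case_id, marker, site, value, imputed`` with ``value`` in 0-20
    (NA where no core was evaluable).
    """
    required = {"case_id", "marker", "site", "replicate", "score"}
    missing = required - set(cores.columns)
    if missing:
        raise ValueError(f"core table lacks columns {sorted(missing)}")
    dup = cores.duplicated(["case_id", "marker", "site", "replicate"])
    if dup.any():
        raise ValueError("duplicate (case, marker, site, replicate) rows")
    rows = []
    for (case, marker, site), grp in cores.groupby(
        ["case_id", "marker", "site"], sort=True
    ):
        value, imputed = aggregate_cores(list(grp["score"]))
        rows.append(
            {"case_id": case, "marker": marker, "site": site,
             "value": value, "imputed": imputed}
        )
    out = pd.DataFrame(rows, columns=["case_id", "marker", "site", "value", "imputed"])
    out["value"] = out["value"].astype("Int64")
    return out


def band(marker: str, value: Optional[int], scheme: BandScheme = DEFAULT_BANDS) -> Optional[str]:
    """Band (``++``/``+``/``-``) of a 0-20 IHC score under ``scheme``."""
    return scheme.band(marker, value)


def classify_group(cdh17_band: str, cldn18_band: str) -> str:
    """Assign the Group 1/2/3/unclassified subgroup from primary-lesion bands.

    Group 1: CDH17 ++ with CLDN18 + or -.
    Group 2: CDH17 ++ with CLDN18 ++, or CDH17 + with CLDN18 +.
    Group 3: CDH17 - (any CLDN18).
    Unclassified: CDH17 + with CLDN18 ++ or -.
    """
    for name, b in (("CDH17", cdh17_band), ("CLDN18", cldn18_band)):
        if b is None:
            raise ValueError(f"cannot classify: {name} band is missing")
        if b not in BANDS:
            raise ValueError(f"unknown band {b!r} for {name}")
    if cdh17_band == BAND_STRONG:
        return GROUP1 if cldn18_band in (BAND_MODERATE, BAND_NEGATIVE) else GROUP2
    if cdh17_band == BAND_MODERATE:
        return GROUP2 if cldn18_band == BAND_MODERATE else UNCLASSIFIED
    return GROUP3


def classify_cases(
    ihc: pd.DataFrame, scheme: BandScheme = DEFAULT_BANDS, site: str = "Pr"
) -> pd.DataFrame:
    """Classify every case of an aggregated IHC table (``aggregate_core_table``).

    Uses CDH17/CLDN18 scores of ``site`` (primary lesion by default). Cases
    with a missing band are reported as unclassified with a reason. Returns
    columns ``case_id, cdh17, cldn18, cdh17_band, cldn18_band, group, reason``.
    """
    sub = ihc[ihc["site"] == site]
    pivot = sub.pivot(index="case_id", columns="marker", values="value")
    rows = []
    for case_id, row in pivot.iterrows():
        scores = {m: row.get(m) for m in ("CDH17", "CLDN18")}
        bands = {m: scheme.band(m, None if pd.isna(v) else int(v))
                 for m, v in scores.items()}
        missing = [m for m, b in bands.items() if b is None]
        if missing:
            group, reason = UNCLASSIFIED, f"missing {'/'.join(missing)} score"
        else:
            group, reason = classify_group(bands["CDH17"], bands["CLDN18"]), ""
        rows.append(
            {"case_id": case_id,
             "cdh17": scores["CDH17"], "cldn18": scores["CLDN18"],
             "cdh17_band": bands["CDH17"], "cldn18_band": bands["CLDN18"],
             "group": group, "reason": reason}
        )
    out = pd.DataFrame(
        rows,
        columns=["case_id", "cdh17", "cldn18", "cdh17_band", "cldn18_band",
                 "group", "reason"],
    )
    for col in ("cdh17", "cldn18"):
        out[col] = out[col].astype("Int64")
    return out


def category(score: int) -> int:
    """Whole-section staining category of a 0-10 score.

    Category 1 (strong, score 8-10), 2 (moderate, 5-7), 3 (weak, 1-4),
    4 (negative, 0).
    """
    s = _check_core(score)
    if s >= 8:
        return 1
    if s >= 5:
        return 2
    if s >= 1:
        return 3
    return 4


@dataclass(frozen=True)
class WholeSectionProfile:
    """Categorized staining pattern of a whole tissue section.

    The primary-lesion cancer area is divided into 10 regions; each region and
    each metastatic node carries one of the four categories.
    """

    case_id: str
    marker: str
    region_categories: tuple[int, ...]
    node_categories: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.region_categories) != 10:
            raise ValueError(
                f"expected 10 primary-lesion regions, got {len(self.region_categories)}"
            )


def whole_section_profile(
    case_id: str,
    marker: str,
    region_scores: Sequence[int],
    node_scores: Sequence[int] = (),
) -> WholeSectionProfile:
    """Categorize the 10 primary-lesion region scores and per-node scores."""
    if len(region_scores) != 10:
        raise ValueError(f"expected 10 region scores, got {len(region_scores)}")
    return WholeSectionProfile(
        case_id=str(case_id),
        marker=str(marker),
        region_categories=tuple(category(s) for s in region_scores),
        node_categories=tuple(category(s) for s in node_scores),
    )
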