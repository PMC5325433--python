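"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Three generators mirror the three kinds of study input:

* an expression matrix (probes x samples of positive, right-skewed MAS5-style
  signal scores over a normal-tissue panel plus tumor samples) with a known
  set of planted tumor-enriched marker probes and decoy probes that each fail
  the screen for exactly one designated reason;
* a TMA core-score table (duplicate 0-10 cores per marker and site, with
  optional missing lymph-node cores) whose primary-lesion aggregates land in
  the score boxes of a chosen latent subgroup;
* exponential time-to-event records with independent exponential censoring
  and an administrative follow-up cap.

All generators draw from a single numpy Generator seeded from their config,
so identical configs give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import ihc
from .screen import (
    DEFAULT_EXCLUDED_TISSUES,
    DEFAULT_NORMAL_PANEL,
    TUMOR_LABEL,
    ExpressionMatrix,
    ScreenThresholds,
)

DECOY_MODES = ("normal_leaky", "tumor_weak", "tumor_rare")

_DEFAULT_TISSUES = tuple(sorted(DEFAULT_NORMAL_PANEL)) + tuple(
    sorted(DEFAULT_EXCLUDED_TISSUES)
)


@dataclass(frozen=True)
class ExpressionFixtureConfig:
    """Parameters of the synthetic expression matrix.

    Background probes follow a log-normal signal (meanlog 3.5, sdlog 1.0 by
    default: median ~33, heavy right tail, far below the screen's tumor
    floor at the required frequency).  Planted markers are silent on the
    normal panel (uniform 1-100) and strong (>= 600) in at least
    ``thresholds.tumor_rank_k`` tumors; each decoy mode violates exactly one
    screen criterion.
    """

    n_probes: int = 10_000
    n_tumors: int = 56
    normal_tissue_names: Sequence[str] = _DEFAULT_TISSUES
    n_planted_markers: int = 3
    decoy_counts: Mapping[str, int] = field(
        default_factory=lambda: {m: 5 for m in DECOY_MODES}
    )
    background_log_mean: float = 3.5
    background_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_tumors < 1:
            raise ValueError("n_probes and n_tumors must be positive")
        if self.n_planted_markers < 0:
            raise ValueError("n_planted_markers must be >= 0")
        unknown = set(self.decoy_counts) - set(DECOY_MODES)
        if unknown:
            raise ValueError(f"unknown decoy modes {sorted(unknown)}")
        if any(c < 0 for c in self.decoy_counts.values()):
            raise ValueError("decoy counts must be >= 0")
        if self.background_log_sd <= 0:
            raise ValueError("background_log_sd must be > 0")
        n_special = self.n_planted_markers + sum(self.decoy_counts.values())
        if n_special > self.n_probes:
            raise ValueError(
                f"planted ({self.n_planted_markers}) + decoy "
                f"({sum(self.decoy_counts.values())}) probes exceed "
                f"n_probes={self.n_probes}"
            )


@dataclass
class ExpressionFixture:
    """Generated matrix plus the ground-truth probe roles."""

    matrix: ExpressionMatrix
    planted_probes: list
    decoy_probes: dict
    config: ExpressionFixtureConfig


_PLANT_NAMES = ("CDH17", "CLDN18", "PRR15")


def generate_expression_fixture(
    config: ExpressionFixtureConfig,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> ExpressionFixture:
    """Generate a matrix in which exactly the planted probes pass the screen."""
    rng = np.random.default_rng(config.seed)
    tissues = [str(t) for t in config.normal_tissue_names]
    sample_ids = [f"N_{t.replace(' ', '_')}" for t in tissues] + [
        f"GC_{i + 1:03d}" for i in range(config.n_tumors)
    ]
    classes = pd.Series(tissues + [TUMOR_LABEL] * config.n_tumors, index=sample_ids)
    norm = classes.map(lambda s: " ".join(str(s).strip().lower().split()))
    panel_mask = norm.isin(thresholds.normal_panel).to_numpy()
    excluded_mask = norm.isin(thresholds.excluded_tissues).to_numpy()
    tumor_mask = (norm == TUMOR_LABEL).to_numpy()
    n_tumor = int(tumor_mask.sum())
    k = thresholds.tumor_rank_k
    if k > n_tumor:
        raise ValueError(f"tumor_rank_k={k} exceeds n_tumors={n_tumor}")
    if not panel_mask.any():
        raise ValueError("no configured tissue belongs to the normal panel")

    n_samples = len(sample_ids)
    n_special = config.n_planted_markers + sum(config.decoy_counts.values())
    n_background = config.n_probes - n_special

    def normal_silent(row: np.ndarray) -> None:
        row[panel_mask] = rng.uniform(1, 100, panel_mask.sum())

    def digestive_high(row: np.ndarray) -> None:
        # stomach/colon/small intestine may be strongly positive; the screen
        # must ignore them.
        row[excluded_mask] = rng.uniform(500, 8000, excluded_mask.sum())

    def tumor_strong(row: np.ndarray) -> None:
        n_high = int(rng.integers(k, n_tumor + 1))
        high = rng.permutation(n_tumor)[:n_high]
        tvals = rng.uniform(1, 400, n_tumor)
        tvals[high] = rng.uniform(600, 6000, n_high)
        row[tumor_mask] = tvals

    rows = []
    probe_ids = []
    for i in range(config.n_planted_markers):
        row = np.empty(n_samples)
        normal_silent(row)
        digestive_high(row)
        tumor_strong(row)
        name = _PLANT_NAMES[i] if i < len(_PLANT_NAMES) else f"PLANTED_{i + 1}"
        probe_ids.append(f"{name}_at")
        rows.append(row)

    for mode in DECOY_MODES:
        for j in range(config.decoy_counts.get(mode, 0)):
            row = np.empty(n_samples)
            digestive_high(row)
            if mode == "normal_leaky":
                normal_silent(row)
                leak = rng.choice(np.flatnonzero(panel_mask))
                row[leak] = rng.uniform(200, 2000)
                tumor_strong(row)
            elif mode == "tumor_weak":
                normal_silent(row)
                row[tumor_mask] = rng.uniform(1, 450, n_tumor)
            else:  # tumor_rare: strong but in too few tumors
                normal_silent(row)
                n_high = int(rng.integers(1, k))  # < k strong tumors
                high = rng.permutation(n_tumor)[:n_high]
                tvals = rng.uniform(1, 450, n_tumor)
                tvals[high] = rng.uniform(600, 6000, n_high)
                row[tumor_mask] = tvals
            probe_ids.append(f"DECOY_{mode}_{j + 1}_at")
            rows.append(row)

    bg = rng.lognormal(
        config.background_log_mean, config.background_log_sd, (n_background, n_samples)
    )
    # Defensive guarantee of the "exactly the planted set" contract: damp the
    # (astronomically unlikely) background row that would pass both criteria.
    if n_background and tumor_mask.any() and panel_mask.any():
        bg_nmax = bg[:, panel_mask].max(axis=1)
        bg_kth = np.sort(bg[:, tumor_mask], axis=1)[:, n_tumor - k]
        bad = (bg_nmax < thresholds.normal_ceiling) & (bg_kth >= thresholds.tumor_floor)
        bg[bad] = bg[bad] * (400.0 / np.maximum(bg[bad].max(axis=1, keepdims=True), 1))
    for j in range(n_background):
        probe_ids.append(f"BG_{j + 1:05d}_at")
        rows.append(bg[j])

    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n_samples)),
                          index=probe_ids, columns=sample_ids).round(1)
    matrix = ExpressionMatrix(values=values, tissue_class=classes)
    n_plant = config.n_planted_markers
    decoys = {}
    pos = n_plant
    for mode in DECOY_MODES:
        c = config.decoy_counts.get(mode, 0)
        decoys[mode] = probe_ids[pos : pos + c]
        pos += c
    return ExpressionFixture(
        matrix=matrix,
        planted_probes=probe_ids[:n_plant],
        decoy_probes=decoys,
        config=config,
    )


#: Latent-group boxes on the (CDH17, CLDN18) primary-lesion aggregate grid.
GROUP_BOXES = {
    ihc.GROUP1: [((18, 20), (0, 13))],
    ihc.GROUP2: [((18, 20), (14, 20)), ((9, 17), (6, 13))],
    ihc.GROUP3: [((0, 8), (0, 20))],
    ihc.UNCLASSIFIED: [((9, 17), (14, 20)), ((9, 17), (0, 5))],
}


@dataclass(frozen=True)
class TMAFixtureConfig:
    """Parameters of the synthetic TMA core-score table.

    ``group_proportions`` weights the latent Group1/Group2/Group3/unclassified
    labels (default: the observed 30/30/38/8 of 106 cases);
    ``replicate_noise`` bounds the core-to-core score difference within a
    duplicate pair; LN cores are deleted independently with
    ``missing_ln_core_rate`` (nodal cores without a cancer component).
    """

    n_cases: int = 106
    group_proportions: Sequence[float] = (30, 30, 38, 8)
    replicate_noise: int = 2
    missing_ln_core_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        w = np.asarray(self.group_proportions, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError(
                "group_proportions must be 4 non-negative weights with positive sum"
            )
        if not 0 <= self.replicate_noise <= 10:
            raise ValueError("replicate_noise must be in 0..10")
        if not 0 <= self.missing_ln_core_rate <= 1:
            raise ValueError("missing_ln_core_rate must be in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        w = np.asarray(self.group_proportions, dtype=float)
        return w / w.sum()


@dataclass
class TMAFixture:
    """Generated core table plus the latent per-case group labels."""

    cores: pd.DataFrame  # case_id, marker, site, replicate, score
    latent_groups: pd.Series
    config: TMAFixtureConfig


def _box_cells(group: str, even_only: bool) -> list[tuple[int, int]]:
    cells = []
    for (c_lo, c_hi), (l_lo, l_hi) in GROUP_BOXES[group]:
        for c in range(c_lo, c_hi + 1):
            for l in range(l_lo, l_hi + 1):
                if even_only and (c % 2 or l % 2):
                    continue
                cells.append((c, l))
    return cells


def _split_aggregate(value: int, noise: int, rng: np.random.Generator) -> tuple[int, int]:
    """Split a 0-20 aggregate into two 0-10 cores differing by <= noise."""
    diffs = [
        d
        for d in range(noise + 1)
        if d % 2 == value % 2 and (value + d) // 2 <= 10 and (value - d) >= 0
    ]
    if not diffs:
        raise ValueError(
            f"aggregate {value} cannot be split with replicate_noise={noise}"
        )
    d = int(rng.choice(diffs))
    hi, lo = (value + d) // 2, (value - d) // 2
    return (hi, lo) if rng.random() < 0.5 else (lo, hi)


def generate_tma_fixture(config: TMAFixtureConfig) -> TMAFixture:
    """Generate duplicate Pr/LN cores per marker whose Pr aggregates sit in
    each case's latent group box."""
    rng = np.random.default_rng(config.seed)
    even_only = config.replicate_noise == 0
    cells = {g: _box_cells(g, even_only) for g in ihc.GROUPS}
    labels = [ihc.GROUPS[i] for i in
              rng.choice(4, size=config.n_cases, p=config.weights)]
    rows = []
    case_ids = [f"case_{i + 1:03d}" for i in range(config.n_cases)]
    for case_id, group in zip(case_ids, labels):
        cdh17_pr, cldn18_pr = cells[group][int(rng.integers(len(cells[group])))]
        # CLDN7 tracks the intestinal marker CDH17 at lower intensity.
        cldn7_pr = int(np.clip(cdh17_pr - rng.integers(0, 6), 0, 20))
        if even_only and cldn7_pr % 2:
            cldn7_pr -= 1
        pr = {"CDH17": cdh17_pr, "CLDN18": cldn18_pr, "CLDN7": cldn7_pr}
        for marker in ihc.MARKERS:
            ln = int(np.clip(pr[marker] + rng.integers(-3, 4), 0, 20))
            if even_only and ln % 2:
                ln -= 1
            for site, agg in (("Pr", pr[marker]), ("LN", ln)):
                c1, c2 = _split_aggregate(agg, config.replicate_noise, rng)
                for replicate, score in ((1, c1), (2, c2)):
                    if site == "LN" and rng.random() < config.missing_ln_core_rate:
                        continue
                    rows.append(
                        {"case_id": case_id, "marker": marker, "site": site,
                         "replicate": replicate, "score": int(score)}
                    )
    cores = pd.DataFrame(rows, columns=["case_id", "marker", "site", "replicate", "score"])
    latent = pd.Series(labels, index=case_ids, name="latent_group")
    return TMAFixture(cores=cores, latent_groups=latent, config=config)


@dataclass(frozen=True)
class SurvivalFixtureConfig:
    """Exponential event times per group with independent exponential censoring
    and an administrative follow-up cap (days)."""

    group_hazards: Mapping[str, float]
    censor_rate: float = 1.0 / 3650.0
    max_followup: float = 3650.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_hazards:
            raise ValueError("group_hazards must not be empty")
        if any(h <= 0 for h in self.group_hazards.values()):
            raise ValueError("all hazards must be > 0")
        if self.censor_rate <= 0:
            raise ValueError("censor_rate must be > 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")


def generate_survival_fixture(
    config: SurvivalFixtureConfig,
    group_labels: Sequence[str],
    case_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Time-to-event records (case_id, time_days, event, group) per label.

    time = min(event time, censor time, max_followup); event=1 only when the
    event time is the minimum.
    """
    unknown = sorted(set(group_labels) - set(config.group_hazards))
    if unknown:
        raise KeyError(
            f"no hazard for group(s) {unknown}; known: {sorted(config.group_hazards)}"
        )
    rng = np.random.default_rng(config.seed)
    n = len(group_labels)
    if case_ids is None:
        case_ids = [f"case_{i + 1:03d}" for i in range(n)]
    hazards = np.array([config.group_hazards[g] for g in group_labels])
    t_event = rng.exponential(1.0 / hazards)
    t_censor = rng.exponential(1.0 / config.censor_rate, n)
    time = np.minimum(np.minimum(t_event, t_censor), config.max_followup)
    event = (t_event <= np.minimum(t_censor, config.max_followup)).astype(int)
    return pd.DataFrame(
        {
            "case_id": list(case_ids),
            "time_days": time,
            "event": event,
            "group": list(group_labels),
        }
    )
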