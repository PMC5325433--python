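"""Order-statistic screen for tumor-enriched, normal-silent membrane markers.

Each probe of a positive expression matrix (MAS5-style signal scores) is
summarized by two statistics: the maximum signal over a panel of normal
tissues that would confound in-vivo nodal detection (digestive-tract tissues
excluded), and the k-th largest signal among the tumor samples.  A probe is a
candidate when the normal-panel maximum stays strictly below a ceiling
(default 150) and the k-th tumor value (default k=40 of 56) reaches the tumor
floor (default 500) — i.e. it is silent where it must be and frequently,
strongly expressed in tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TUMOR_LABEL = "tumor"

DEFAULT_NORMAL_PANEL = frozenset(
    {
        "esophagus",
        "pancreas",
        "spleen",
        "adipose",
        "lymph node",
        "artery",
        "vein",
        "peripheral blood cells",
        "monocyte",
        "macrophage",
    }
)
#: Digestive-tract tissues where the markers are physiologically expressed;
#: ignored by the normal-panel maximum.
DEFAULT_EXCLUDED_TISSUES = frozenset({"stomach", "colon", "small intestine"})


def _norm_label(label: object) -> str:
    return " ".join(str(label).strip().lower().split())


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of non-negative signal scores with tissue labels.

    ``values`` is indexed by probe id with one column per sample id;
    ``tissue_class`` maps each sample id to ``"tumor"`` or a normal-tissue
    name (matched case-insensitively, whitespace-collapsed).
    """

    values: pd.DataFrame
    tissue_class: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.tissue_class = pd.Series(self.tissue_class)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.tissue_class.index]
        if missing:
            raise ValueError(f"samples without tissue class: {missing[:5]}")
        self.tissue_class = self.tissue_class.reindex(self.values.columns)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signal scores must be non-negative")
        self.values.index.name = "probe_id"

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def normalized_classes(self) -> pd.Series:
        return self.tissue_class.map(_norm_label)


@dataclass(frozen=True)
class ScreenThresholds:
    """Selection rule of the screen.

    A probe passes when normal-panel max < ``normal_ceiling`` (strict) and the
    ``tumor_rank_k``-th largest tumor value >= ``tumor_floor`` (inclusive).
    """

    normal_ceiling: float = 150.0
    tumor_floor: float = 500.0
    tumor_rank_k: int = 40
    normal_panel: frozenset = DEFAULT_NORMAL_PANEL
    excluded_tissues: frozenset = DEFAULT_EXCLUDED_TISSUES

    def __post_init__(self) -> None:
        if self.tumor_rank_k < 1:
            raise ValueError("tumor_rank_k must be >= 1")
        panel = frozenset(_norm_label(t) for t in self.normal_panel)
        excluded = frozenset(_norm_label(t) for t in self.excluded_tissues)
        object.__setattr__(self, "normal_panel", panel)
        object.__setattr__(self, "excluded_tissues", excluded)
        if TUMOR_LABEL in panel or TUMOR_LABEL in excluded:
            raise ValueError("'tumor' cannot appear in a normal tissue set")


@dataclass
class ScreenResult:
    """Per-probe screen statistics and the selected candidate set."""

    table: pd.DataFrame  # normal_max, tumor_kth, pass_normal, pass_tumor, selected
    thresholds: ScreenThresholds
    selected_probes: list = field(init=False)

    def __post_init__(self) -> None:
        self.selected_probes = sorted(self.table.index[self.table["selected"]])


def _sample_masks(
    matrix: ExpressionMatrix, thresholds: ScreenThresholds
) -> tuple[np.ndarray, np.ndarray]:
    classes = matrix.normalized_classes()
    known = thresholds.normal_panel | thresholds.excluded_tissues | {TUMOR_LABEL}
    unknown = sorted(set(classes) - known)
    if unknown:
        warnings.warn(
            f"ignoring samples with tissue classes outside the screen vocabulary: "
            f"{unknown}",
            stacklevel=3,
        )
    panel = classes.isin(thresholds.normal_panel).to_numpy()
    tumor = (classes == TUMOR_LABEL).to_numpy()
    return panel, tumor


def normal_max(
    matrix: ExpressionMatrix, probe, thresholds: ScreenThresholds = ScreenThresholds()
) -> float:
    """Maximum signal of ``probe`` over the normal panel (exclusions ignored)."""
    panel, _ = _sample_masks(matrix, thresholds)
    if not panel.any():
        raise ValueError("no samples belong to the normal panel")
    return float(matrix.values.loc[probe].to_numpy()[panel].max())


def tumor_order_stat(matrix: ExpressionMatrix, probe, k: int) -> float:
    """k-th largest tumor signal of ``probe`` (1-based, ties counted)."""
    tumor = (matrix.normalized_classes() == TUMOR_LABEL).to_numpy()
    n_tumor = int(tumor.sum())
    if not 1 <= k <= n_tumor:
        raise ValueError(f"k={k} out of range for {n_tumor} tumor samples")
    vals = matrix.values.loc[probe].to_numpy()[tumor]
    return float(np.sort(vals)[n_tumor - k])


def screen(
    matrix: ExpressionMatrix, thresholds: ScreenThresholds = ScreenThresholds()
) -> ScreenResult:
    """Run the two-threshold screen over every probe of ``matrix``."""
    panel, tumor = _sample_masks(matrix, thresholds)
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("matrix contains no tumor samples")
    if not panel.any():
        raise ValueError("no samples belong to the normal panel")
    k = thresholds.tumor_rank_k
    if k > n_tumor:
        raise ValueError(f"tumor_rank_k={k} exceeds {n_tumor} tumor samples")

    values = matrix.values.to_numpy(dtype=float)
    nmax = values[:, panel].max(axis=1)
    tumor_sorted = np.sort(values[:, tumor], axis=1)
    kth = tumor_sorted[:, n_tumor - k]
    pass_normal = nmax < thresholds.normal_ceiling
    pass_tumor = kth >= thresholds.tumor_floor
    table = pd.DataFrame(
        {
            "normal_max": nmax,
            "tumor_kth": kth,
            "pass_normal": pass_normal,
            "pass_tumor": pass_tumor,
            "selected": pass_normal & pass_tumor,
        },
        index=matrix.values.index.rename("probe_id"),
    )
    return ScreenResult(table=table, thresholds=thresholds)


def scatter_table(result: ScreenResult) -> pd.DataFrame:
    """Flat per-probe table (probe_id, normal_max, tumor_kth, selected).

    One row per probe, reproducing the screen's scatter axes; suitable for TSV
    export and plotting.
    """
    out = result.table[["normal_max", "tumor_kth", "selected"]].reset_index()
    return out
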