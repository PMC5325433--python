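"""Readers and writers for the pipeline's plain-text formats.

Conventions: CSV is comma-separated UTF-8 with a mandatory header; expression
matrices are TSV (wide).  Every writer prepends '#'-prefixed provenance
comment lines (tool version, seed, config hash) which the readers skip, and
JSON outputs carry a ``provenance`` object instead.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .cluster import Dendrogram, TwoWayResult, to_newick
from .coverage import PanelCoverageResult
from .screen import ExpressionMatrix, ScreenResult
from .survival import KMCurve


def provenance(seed: Optional[int] = None, config: Optional[dict] = None) -> dict:
    info = {"tool": "gcmarkers", "version": __version__}
    if seed is not None:
        info["seed"] = seed
    if config:
        blob = json.dumps(config, sort_keys=True, default=str)
        info["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return info


def _header_lines(prov: Optional[dict]) -> str:
    if not prov:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


def _write_table(
    df: pd.DataFrame, path, sep: str, prov: Optional[dict], index: bool
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(prov))
        df.to_csv(fh, sep=sep, index=index)


def write_csv(df: pd.DataFrame, path, prov: Optional[dict] = None, index: bool = False) -> None:
    _write_table(df, path, ",", prov, index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_json(obj: dict, path, prov: Optional[dict] = None) -> None:
    payload = dict(obj)
    if prov:
        payload["provenance"] = prov
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# -- expression -------------------------------------------------------------

def write_expression(
    matrix: ExpressionMatrix, values_tsv, samples_csv, prov: Optional[dict] = None
) -> None:
    """Write the probes x samples TSV and the sample-sheet CSV."""
    df = matrix.values.copy()
    df.index.name = "probe_id"
    _write_table(df, values_tsv, "\t", prov, index=True)
    sheet = matrix.tissue_class.rename("tissue_class").rename_axis("sample_id").reset_index()
    write_csv(sheet, samples_csv, prov)


def read_expression(values_tsv, samples_csv) -> ExpressionMatrix:
    values = pd.read_csv(values_tsv, sep="\t", comment="#", index_col="probe_id")
    sheet = read_csv(samples_csv)
    _require_columns(sheet, {"sample_id", "tissue_class"}, samples_csv)
    classes = sheet.set_index("sample_id")["tissue_class"]
    return ExpressionMatrix(values=values, tissue_class=classes)


def write_screen_result(
    result: ScreenResult, table_tsv, summary_json, prov: Optional[dict] = None
) -> None:
    _write_table(result.table, table_tsv, "\t", prov, index=True)
    summary = {
        "n_probes": int(len(result.table)),
        "n_pass_normal": int(result.table["pass_normal"].sum()),
        "n_pass_tumor": int(result.table["pass_tumor"].sum()),
        "n_selected": int(result.table["selected"].sum()),
        "selected_probes": list(map(str, result.selected_probes)),
        "thresholds": {
            "normal_ceiling": result.thresholds.normal_ceiling,
            "tumor_floor": result.thresholds.tumor_floor,
            "tumor_rank_k": result.thresholds.tumor_rank_k,
        },
    }
    write_json(summary, summary_json, prov)


# -- IHC / TMA --------------------------------------------------------------

_CORE_COLUMNS = {"case_id", "marker", "site", "replicate", "score"}


def _require_columns(df: pd.DataFrame, required: set, path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")


def write_core_scores(cores: pd.DataFrame, path, prov: Optional[dict] = None) -> None:
    write_csv(cores, path, prov)


def read_core_scores(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, _CORE_COLUMNS, path)
    for i, row in df.iterrows():
        s = row["score"]
        if pd.isna(s) or float(s) != int(s) or not 0 <= int(s) <= 10:
            raise ValueError(
                f"{path}: line {i + 2}, column 'score': invalid core score {s!r} "
                "(expected integer 0-10)"
            )
        if row["site"] not in ("Pr", "LN"):
            raise ValueError(
                f"{path}: line {i + 2}, column 'site': {row['site']!r} "
                "(expected 'Pr' or 'LN')"
            )
    df["score"] = df["score"].astype(int)
    return df


def read_clinical(path) -> pd.DataFrame:
    df = read_csv(path)
    _require_columns(df, {"case_id", "time_days", "event"}, path)
    bad = df.index[(df["time_days"] <= 0) | ~df["event"].isin((0, 1))]
    if len(bad):
        raise ValueError(
            f"{path}: line {bad[0] + 2}: time_days must be > 0 and event in {{0,1}}"
        )
    return df


def write_whole_section_profiles(profiles, path, prov: Optional[dict] = None) -> None:
    """Whole-section category profiles as JSON (10 regions + per-node)."""
    payload = {
        "profiles": [
            {
                "case_id": p.case_id,
                "marker": p.marker,
                "region_categories": list(p.region_categories),
                "node_categories": list(p.node_categories),
            }
            for p in profiles
        ]
    }
    write_json(payload, path, prov)


# -- coverage ---------------------------------------------------------------

def write_coverage(
    result: PanelCoverageResult, json_path, patterns_csv=None, prov: Optional[dict] = None
) -> None:
    payload = {
        "panel": list(result.panel),
        "covered": result.covered,
        "total": result.total,
        "fraction": result.fraction,
        "percent": result.percent(),
    }
    write_json(payload, json_path, prov)
    if patterns_csv is not None:
        rows = [
            {
                **{m: ("+" if p else "-") for m, p in zip(result.panel, pat)},
                "count": n,
            }
            for pat, n in sorted(result.pattern_counts.items(), reverse=True)
        ]
        write_csv(pd.DataFrame(rows), patterns_csv, prov)


# -- clustering -------------------------------------------------------------

def write_newick(dendrogram: Dendrogram, labels, path) -> None:
    Path(path).write_text(to_newick(dendrogram, labels) + "\n")


def _tree_table(tree: Dendrogram, prefix: str) -> pd.DataFrame:
    """Merge list in the GTR/ATR style of TreeView tree files."""
    n = tree.n_leaves

    def name(node: int) -> str:
        return f"{prefix}LEAF{node}" if node < n else f"{prefix}NODE{node - n}"

    rows = [
        {"node": name(n + i), "left": name(l), "right": name(r), "height": h}
        for i, (l, r, h, _) in enumerate(tree.merges)
    ]
    return pd.DataFrame(rows, columns=["node", "left", "right", "height"])


def write_clustered_tables(
    result: TwoWayResult, prefix, prov: Optional[dict] = None
) -> dict:
    """Write the reordered matrix (.cdt-style TSV) and row/column tree files.

    Mirrors the clustered-data-table + gene/array tree convention of
    TreeView-style viewers; returns the written paths.
    """
    prefix = Path(prefix)
    paths = {
        "cdt": prefix.with_suffix(".cdt.tsv"),
        "gtr": prefix.with_suffix(".gtr.tsv"),
        "atr": prefix.with_suffix(".atr.tsv"),
        "row_newick": prefix.with_suffix(".rows.nwk"),
        "col_newick": prefix.with_suffix(".cols.nwk"),
    }
    reordered = result.reordered.copy()
    reordered.index.name = reordered.index.name or "id"
    _write_table(reordered, paths["cdt"], "\t", prov, index=True)
    _write_table(_tree_table(result.row_tree, "G"), paths["gtr"], "\t", prov, index=False)
    _write_table(_tree_table(result.col_tree, "A"), paths["atr"], "\t", prov, index=False)
    write_newick(result.row_tree, [str(i) for i in result.transformed.index], paths["row_newick"])
    write_newick(result.col_tree, [str(c) for c in result.transformed.columns], paths["col_newick"])
    return {k: str(v) for k, v in paths.items()}


# -- survival ---------------------------------------------------------------

def write_km_csv(curve: KMCurve, path, prov: Optional[dict] = None) -> None:
    df = pd.DataFrame(
        {
            "time": curve.timeline,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "n_events": curve.n_events,
        }
    )
    write_csv(df, path, prov)
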