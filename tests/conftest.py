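import numpy as np
import pandas as pd
import pytest

from gcmarkers import ExpressionMatrix, ScreenThresholds


def make_matrix(values: np.ndarray, tissues, probe_ids=None) -> ExpressionMatrix:
    """Small expression matrix from an array and per-sample tissue labels."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_probes, n_samples = values.shape
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(n_probes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        tissue_class=pd.Series(list(tissues), index=sample_ids),
    )


def brute_force_screen(matrix: ExpressionMatrix, thresholds: ScreenThresholds):
    """Independent double-loop filter: plain-python re-derivation of the screen."""
    classes = [
        " ".join(str(c).strip().lower().split()) for c in matrix.tissue_class
    ]
    selected = []
    stats = {}
    for probe in matrix.probe_ids:
        row = matrix.values.loc[probe]
        panel_vals = [
            v for v, c in zip(row, classes) if c in thresholds.normal_panel
        ]
        tumor_vals = sorted(
            (v for v, c in zip(row, classes) if c == "tumor"), reverse=True
        )
        nmax = max(panel_vals)
        kth = tumor_vals[thresholds.tumor_rank_k - 1]
        stats[probe] = (nmax, kth)
        if nmax < thresholds.normal_ceiling and kth >= thresholds.tumor_floor:
            selected.append(probe)
    return sorted(selected), stats


def random_labeled_matrix(rng: np.random.Generator, n_probes, n_normals, n_tumors):
    """Random positive matrix over a normal panel + excluded tissues + tumors."""
    panel = sorted(ScreenThresholds().normal_panel)
    excluded = sorted(ScreenThresholds().excluded_tissues)
    tissues = [panel[i % len(panel)] for i in range(n_normals)] + excluded
    tissues += ["tumor"] * n_tumors
    values = rng.lognormal(4.0, 2.0, (n_probes, len(tissues)))
    return make_matrix(values, tissues)


@pytest.fixture
def rng():
    return np.random.default_rng(20160826)
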