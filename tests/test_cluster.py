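"""Clustering: transform, NaN-aware distances, UPGMA vs oracles, two-way."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from gcmarkers import (
    DistanceMatrix,
    average_linkage,
    cityblock_distance,
    correlation_distance,
    cut_tree,
    log150_transform,
    pairwise_distances,
    to_newick,
    two_way_cluster,
)


@pytest.mark.parametrize("x,expected", [(150, 1.0), (1, 0.0), (22500, 2.0), (0, 0.0),
                                        (0.5, 0.0)])
def test_log150_values(x, expected):
    assert log150_transform(x) == pytest.approx(expected)


def test_log150_rejects_negative():
    with pytest.raises(ValueError):
        log150_transform(-1.0)


def test_cityblock_mean_convention():
    assert cityblock_distance([1, 2], [4, 6]) == pytest.approx(3.5)
    assert cityblock_distance([1, 2, 3], [1, 2, 3]) == 0.0


def test_cityblock_pairwise_complete():
    a = [1.0, np.nan, 3.0]
    b = [2.0, 5.0, np.nan]
    assert cityblock_distance(a, b) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cityblock_distance([np.nan, 1.0], [2.0, np.nan])


def test_correlation_distance_limits():
    b = np.array([1.0, 2.0, 5.0, 3.0])
    assert correlation_distance(2 * b + 1, b) == pytest.approx(0.0)
    assert correlation_distance(-b, b) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        correlation_distance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_correlation_matches_pearson_oracle(rng):
    for _ in range(10):
        a, b = rng.normal(size=12), rng.normal(size=12)
        r, _ = pearsonr(a, b)
        assert correlation_distance(a, b) == pytest.approx(1 - r)
        cos = a @ b / np.sqrt((a @ a) * (b @ b))
        assert correlation_distance(a, b, centered=False) == pytest.approx(1 - cos)


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
    st.data(),
)
def test_cityblock_symmetric_nonnegative_identity(a, data):
    b = data.draw(st.lists(st.floats(-1e6, 1e6), min_size=len(a), max_size=len(a)))
    d = cityblock_distance(a, b)
    assert d >= 0
    assert cityblock_distance(b, a) == d
    assert cityblock_distance(a, a) == 0.0


def hand_matrix():
    return DistanceMatrix(np.array([[0.0, 2, 4], [2, 0, 6], [4, 6, 0]]), "cityblock")


def test_average_linkage_hand_example():
    dend = average_linkage(hand_matrix())
    assert dend.merges[0][:3] == (0, 1, 2.0)
    assert dend.merges[1][2] == pytest.approx(5.0)  # (4+6)/2


def test_duplicate_items_merge_at_zero():
    X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
    dend = average_linkage(pairwise_distances(X, "cityblock"))
    assert dend.merges[0][2] == 0.0


def naive_upgma_heights(D: np.ndarray):
    """O(n^3) re-scan agglomeration recomputing every cluster-pair mean."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return heights


@pytest.mark.parametrize("seed", range(10))
def test_average_linkage_matches_naive_rescan(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 13))
    X = rng.normal(size=(n, 5))
    dm = pairwise_distances(X, "cityblock")
    dend = average_linkage(dm)
    expected = naive_upgma_heights(dm.values)
    assert [m[2] for m in dend.merges] == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(5))
def test_average_linkage_matches_scipy_on_complete_data(seed):
    rng = np.random.default_rng(seed + 100)
    X = rng.normal(size=(10, 4))
    dm = pairwise_distances(X, "cityblock")
    Z = linkage(squareform(dm.values, checks=False), method="average")
    dend = average_linkage(dm)
    assert [m[2] for m in dend.merges] == pytest.approx(sorted(Z[:, 2]))


def test_merge_heights_monotone(rng):
    X = rng.normal(size=(15, 6))
    dend = average_linkage(pairwise_distances(X, "cityblock"))
    heights = [m[2] for m in dend.merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))


def test_cut_tree_labels():
    dend = average_linkage(hand_matrix())
    assert len(set(cut_tree(dend, 1))) == 1
    assert len(set(cut_tree(dend, 3))) == 3
    labels = cut_tree(dend, 2)
    assert labels[0] == labels[1] != labels[2]
    with pytest.raises(ValueError):
        cut_tree(dend, 4)


def test_two_way_cluster_separates_blocks(rng):
    block_a = rng.normal(0.0, 0.1, size=(5, 4))
    block_b = rng.normal(10.0, 0.1, size=(5, 4))
    df = pd.DataFrame(np.vstack([block_a, block_b]),
                      index=[f"c{i}" for i in range(10)])
    res = two_way_cluster(df, row_metric="cityblock", col_metric="cityblock")
    labels = cut_tree(res.row_tree, 2)
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[9]
    # reordering conserves the multiset of values
    assert sorted(res.reordered.to_numpy().ravel()) == pytest.approx(
        sorted(df.to_numpy().ravel())
    )


def test_two_way_cluster_recovers_latent_groups_exactly():
    """Noiseless group-structured IHC-like matrix: cutting at k recovers the
    generating partition (adjusted Rand = 1)."""
    from sklearn.metrics import adjusted_rand_score

    patterns = {"g1": [20, 4, 16], "g2": [12, 10, 10], "g3": [2, 18, 2]}
    rows, truth = [], []
    for g, pat in patterns.items():
        for _ in range(6):
            rows.append(pat)
            truth.append(g)
    df = pd.DataFrame(rows, columns=["CDH17", "CLDN18", "CLDN7"], dtype=float)
    res = two_way_cluster(df, row_metric="cityblock", col_metric="cityblock")
    assert adjusted_rand_score(truth, cut_tree(res.row_tree, 3)) == 1.0


def test_two_way_cluster_rejects_all_missing_row():
    df = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan], [3.0, 1.0]],
                      index=["a", "bad", "c"])
    with pytest.raises(ValueError, match="bad"):
        two_way_cluster(df, col_metric="cityblock")


def test_newick_export_is_parseable():
    from io import StringIO

    from Bio import Phylo

    dend = average_linkage(hand_matrix())
    nwk = to_newick(dend, ["A", "B", "C"])
    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
    depths = tree.depths()
    leaf_depths = {t.name: d for t, d in depths.items() if t.name}
    assert leaf_depths["A"] == pytest.approx(5.0)  # root height
    assert leaf_depths["C"] == pytest.approx(5.0)
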