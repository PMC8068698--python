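"""Unit tests for mutual clusters, TSVQ, hybrid trees and cluster diagnostics."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from devprofiles.clustering import (
    calinski_harabasz,
    ch_profile,
    cluster_profiles,
    cut_tree,
    d_stars,
    hybrid_tree,
    maximal_mutual_clusters,
    mutual_clusters,
    silhouette,
    tsvq_tree,
)
from devprofiles.pipeline import adjusted_rand_index


def brute_force_mutual_clusters(D):
    n = D.shape[0]
    out = set()
    for r in range(2, n):
        for S in itertools.combinations(range(n), r):
            S = list(S)
            comp = [i for i in range(n) if i not in S]
            if D[np.ix_(S, S)].max() < D[np.ix_(S, comp)].min():
                out.add(frozenset(S))
    return out


def _blobs(rng, centers, n, scale=0.5):
    centers = np.asarray(centers, dtype=float)
    lab = rng.integers(0, len(centers), n)
    return centers[lab] + rng.normal(scale=scale, size=(n, centers.shape[1])), lab


# ---------------------------------------------------------------- mutual clusters


def test_mutual_clusters_match_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(15):
        P = rng.normal(size=(9, 2))
        D = squareform(pdist(P))
        assert set(mutual_clusters(D)) == brute_force_mutual_clusters(D)


def test_mutual_clusters_worked_example():
    D = squareform(pdist(np.array([[0.0], [1.0], [10.0], [11.0]])))
    assert {frozenset(s) for s in mutual_clusters(D)} == {
        frozenset({0, 1}),
        frozenset({2, 3}),
    }
    assert {frozenset(s) for s in maximal_mutual_clusters(D)} == {
        frozenset({0, 1}),
        frozenset({2, 3}),
    }


def test_mutual_clusters_tiny_and_invalid_input():
    assert mutual_clusters(np.zeros((2, 2))) == []
    with pytest.raises(ValueError):
        mutual_clusters(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric


# ---------------------------------------------------------------- trees


def test_tsvq_recovers_three_blobs():
    rng = np.random.default_rng(1)
    P, lab = _blobs(rng, [[0, 0], [10, 0], [0, 10]], 300)
    part = cut_tree(tsvq_tree(P, seed=1), 3)
    assert adjusted_rand_index(part.labels, lab) == 1.0


def test_hybrid_recovers_four_blobs():
    rng = np.random.default_rng(2)
    P, lab = _blobs(rng, [[0, 0], [8, 0], [0, 8], [8, 8]], 400)
    tree = hybrid_tree(P, seed=2)
    part = cut_tree(tree, 4)
    assert adjusted_rand_index(part.labels, lab) >= 0.95


def test_hybrid_tree_deterministic():
    rng = np.random.default_rng(3)
    P, _ = _blobs(rng, [[0, 0], [6, 0], [0, 6]], 150)
    t1 = hybrid_tree(P, seed=9)
    t2 = hybrid_tree(P, seed=9)
    assert t1.to_merge_list() == t2.to_merge_list()


def test_mutual_clusters_are_contiguous_subtrees():
    rng = np.random.default_rng(4)
    P, _ = _blobs(rng, [[0, 0], [5, 0], [0, 5], [5, 5]], 120)
    tree = hybrid_tree(P, seed=4)
    D = squareform(pdist(P))
    node_sets = {frozenset(int(i) for i in nd.leaves) for nd in tree.internal_nodes()}
    for mc in maximal_mutual_clusters(D):
        assert len(mc) == 1 or mc in node_sets


def test_cut_tree_partitions_are_nested():
    rng = np.random.default_rng(5)
    P, _ = _blobs(rng, [[0, 0], [4, 0], [0, 4]], 90)
    tree = hybrid_tree(P, seed=5)
    prev = cut_tree(tree, 2).labels
    for k in range(3, 9):
        cur = cut_tree(tree, k).labels
        # Nested: each cluster at k lies inside one cluster at k-1.
        for c in np.unique(cur):
            assert np.unique(prev[cur == c]).size == 1
        prev = cur


def test_cut_tree_label_convention():
    rng = np.random.default_rng(6)
    P, _ = _blobs(rng, [[0, 0], [9, 9]], 50)
    part = cut_tree(hybrid_tree(P, seed=6), 3)
    assert part.k == 3
    assert set(np.unique(part.labels)) == {1, 2, 3}
    assert part.labels[0] == 1  # cluster ids ordered by smallest member index


def test_tree_heights_monotone():
    rng = np.random.default_rng(7)
    P, _ = _blobs(rng, [[0, 0], [7, 0], [0, 7]], 100)
    for tree in (tsvq_tree(P, seed=7), hybrid_tree(P, seed=7)):
        for nd in tree.internal_nodes():
            for child in (nd.left, nd.right):
                if child is not None and child.height is not None:
                    assert child.height <= nd.height + 1e-9


# ---------------------------------------------------------------- diagnostics


def test_calinski_harabasz_worked_example():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([1, 1, 2, 2])
    assert calinski_harabasz(X, labels) == pytest.approx(200.0)


def test_calinski_harabasz_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(8)
    P, lab = _blobs(rng, [[0, 0], [3, 0], [0, 3]], 200)
    assert calinski_harabasz(P, lab) == pytest.approx(
        sk.calinski_harabasz_score(P, lab), rel=1e-10
    )


def test_silhouette_matches_sklearn():
    sk = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(9)
    P, lab = _blobs(rng, [[0, 0], [3, 0], [0, 3]], 150)
    res = silhouette(squareform(pdist(P)), lab)
    assert res["mean"] == pytest.approx(sk.silhouette_score(P, lab), rel=1e-10)
    np.testing.assert_allclose(
        res["per_subject"], sk.silhouette_samples(P, lab), atol=1e-10
    )


def test_ch_profile_marks_extrema():
    rng = np.random.default_rng(10)
    P, _ = _blobs(rng, [[0, 0], [12, 0], [0, 12]], 300)
    tree = hybrid_tree(P, seed=10)
    prof = ch_profile(P, tree, range(2, 7))
    ks = sorted(prof["ch"])
    assert max(prof["ch"], key=prof["ch"].get) == 3
    assert prof["extrema"].get(3) == "maximum"
    # forward percent change is undefined at the last k
    assert ks[-1] not in prof["percent_change"]
    assert prof["percent_change"][3] == pytest.approx(
        100.0 * (prof["ch"][4] - prof["ch"][3]) / prof["ch"][3]
    )


def test_cluster_profiles_and_stars():
    rng = np.random.default_rng(11)
    X = np.concatenate([rng.normal(0, 1, (200, 2)), rng.normal([3, 0], 1, (100, 2))])
    labels = np.array([1] * 200 + [2] * 100)
    from devprofiles.clustering import Partition

    profs = cluster_profiles(X, Partition(labels=labels, k=2))
    assert [p.cluster for p in profs] == [1, 2]
    assert profs[0].size == 200 and profs[1].share == pytest.approx(1 / 3)
    # Cluster 2 is far above the sample mean on factor 1 -> **/*** star label.
    assert profs[1].stars[0] in ("**", "***")
    assert d_stars(0.19) == "" and d_stars(0.21) == "*"
    assert d_stars(0.51) == "**" and d_stars(0.81) == "***"
    assert d_stars(-0.9) == "***"  # magnitude-based
    assert d_stars(0.2) == "" and d_stars(0.5) == "*" and d_stars(0.8) == "**"
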