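"""Hybrid hierarchical clustering (mutual clusters + TSVQ) and diagnostics.

The hybrid scheme combines the strengths of agglomerative and divisive
clustering: *mutual clusters* — point sets whose largest internal distance is
smaller than their smallest distance to any outside point — are found first
and are never broken; each maximal mutual cluster is collapsed to a weighted
centroid, a divisive tree-structured vector quantisation (recursive weighted
2-means) tree is grown over the collapsed points, and each mutual cluster's
own divisive tree is grafted back at its leaf.  Node heights are weighted
within-node sums of squares, capped by the parent height so the dendrogram is
monotone.

Also here: cutting a dendrogram to k clusters, Calinski-Harabasz profiles,
silhouette coefficients, and per-cluster factor-score profiles with Cohen's-d
star labels.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class _Node:
    order: int                 # creation order (root = 0)
    height: float
    leaves: np.ndarray         # original point indices under this node
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class Dendrogram:
    """Binary merge tree over n leaves with non-negative node heights."""

    root: _Node
    n_leaves: int
    leaf_ids: np.ndarray

    def internal_nodes(self) -> list[_Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def to_merge_list(self) -> list[dict]:
        """JSON-serialisable merge list (one entry per internal node)."""
        return [
            {
                "order": n.order,
                "height": float(n.height),
                "leaves": sorted(int(i) for i in n.leaves),
            }
            for n in sorted(self.internal_nodes(), key=lambda n: n.order)
        ]

    def to_linkage(self) -> np.ndarray:
        """Export as a scipy-style linkage matrix (merges sorted by height)."""
        nodes = sorted(self.internal_nodes(), key=lambda n: (n.height, -n.order))
        ids: dict[int, int] = {}
        next_id = self.n_leaves
        Z = np.zeros((len(nodes), 4))

        def node_id(node: _Node) -> int:
            if node.is_leaf:
                return int(node.leaves[0])
            return ids[node.order]

        for row, n in enumerate(nodes):
            a, b = node_id(n.left), node_id(n.right)
            Z[row] = [min(a, b), max(a, b), n.height, len(n.leaves)]
            ids[n.order] = next_id
            next_id += 1
        return Z


@dataclass
class Partition:
    labels: np.ndarray  # 1..k per subject
    k: int


@dataclass
class ClusterProfile:
    cluster: int
    size: int
    share: float
    factor_means: np.ndarray
    cohens_d: np.ndarray
    stars: list[str]


def d_stars(d: float) -> str:
    """Effect-size star label: *** |d|>0.8, ** |d|>0.5, * |d|>0.2 (strict)."""
    a = abs(d)
    if a > 0.8:
        return "***"
    if a > 0.5:
        return "**"
    if a > 0.2:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Mutual clusters
# ---------------------------------------------------------------------------

def mutual_clusters(dist: np.ndarray) -> list[frozenset]:
    """All mutual clusters of a symmetric distance matrix.

    A set S (2 <= |S| < n) is a mutual cluster when its largest internal
    distance is strictly smaller than its smallest distance to the complement.
    Mutual clusters are nested and are never broken by average-linkage
    agglomeration, so scanning the nodes of an average-linkage tree and
    verifying the definition directly finds them all.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dist must be a symmetric square matrix")
    if n < 3:
        return []
    Z = linkage(squareform(D, checks=False), method="average")
    # Leaf sets of every internal node.
    sets: list[np.ndarray] = []
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for row in range(Z.shape[0]):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        merged = np.concatenate([members[a], members[b]])
        members[n + row] = merged
        if 2 <= merged.size < n:
            sets.append(np.sort(merged))
    out = []
    all_idx = np.arange(n)
    for S in sets:
        comp = np.setdiff1d(all_idx, S, assume_unique=True)
        max_in = D[np.ix_(S, S)].max()
        min_out = D[np.ix_(S, comp)].min()
        if max_in < min_out:
            out.append(frozenset(int(i) for i in S))
    return out


def maximal_mutual_clusters(dist: np.ndarray) -> list[frozenset]:
    mcs = mutual_clusters(dist)
    return [s for s in mcs if not any(s < t for t in mcs)]


# ---------------------------------------------------------------------------
# TSVQ divisive tree
# ---------------------------------------------------------------------------

def _weighted_sse(points: np.ndarray, weights: np.ndarray) -> float:
    centroid = np.average(points, axis=0, weights=weights)
    return float(np.sum(weights * np.sum((points - centroid) ** 2, axis=1)))


def _two_means(points: np.ndarray, weights: np.ndarray, rng: np.random.Generator,
               n_restarts: int) -> np.ndarray:
    """Weighted 2-means labels (0/1) with k-means++-style restarts.

    Ties in assignment break toward the lower-index centroid; the best restart
    is the first one attaining the minimal weighted within-SSE.
    """
    m = points.shape[0]
    best_labels = None
    best_sse = np.inf
    prob = weights / weights.sum()
    for _ in range(n_restarts):
        i0 = rng.choice(m, p=prob)
        d2 = np.sum((points - points[i0]) ** 2, axis=1)
        w2 = prob * d2
        if w2.sum() <= 0:
            break
        i1 = rng.choice(m, p=w2 / w2.sum())
        centers = points[[i0, i1]].astype(float)
        labels = np.zeros(m, dtype=int)
        for it in range(100):
            d = np.stack(
                [np.sum((points - centers[0]) ** 2, axis=1),
                 np.sum((points - centers[1]) ** 2, axis=1)]
            )
            new_labels = np.argmin(d, axis=0)  # argmin ties -> lower index
            if it > 0 and np.all(new_labels == labels):
                break
            labels = new_labels
            for c in (0, 1):
                sel = labels == c
                if sel.any():
                    centers[c] = np.average(points[sel], axis=0, weights=weights[sel])
        if labels.min() == labels.max():
            continue
        sse = sum(
            _weighted_sse(points[labels == c], weights[labels == c]) for c in (0, 1)
        )
        if sse < best_sse - 1e-12:
            best_sse = sse
            best_labels = labels.copy()
    if best_labels is None:
        # Zero-variance (or degenerate) node: split by index order.
        best_labels = np.zeros(m, dtype=int)
        best_labels[m // 2:] = 1
    return best_labels


class _Counter:
    def __init__(self):
        self.value = 0

    def next(self) -> int:
        v = self.value
        self.value += 1
        return v


def _build_tsvq(points: np.ndarray, weights: np.ndarray, idx: np.ndarray,
                rng: np.random.Generator, n_restarts: int, parent_height: float,
                counter: _Counter) -> _Node:
    order = counter.next()
    if idx.size == 1 and weights[0] <= 1:
        return _Node(order=order, height=0.0, leaves=idx.copy())
    if idx.size == 1:
        # Weighted singleton (collapsed mutual cluster placeholder) is a leaf.
        return _Node(order=order, height=0.0, leaves=idx.copy())
    height = min(_weighted_sse(points, weights), parent_height)
    if np.allclose(points, points[0]):
        labels = np.zeros(idx.size, dtype=int)
        labels[idx.size // 2:] = 1
        height = 0.0
    else:
        labels = _two_means(points, weights, rng, n_restarts)
    node = _Node(order=order, height=height, leaves=idx.copy())
    left_sel, right_sel = labels == 0, labels == 1
    node.left = _build_tsvq(
        points[left_sel], weights[left_sel], idx[left_sel], rng, n_restarts, height, counter
    )
    node.right = _build_tsvq(
        points[right_sel], weights[right_sel], idx[right_sel], rng, n_restarts, height, counter
    )
    return node


def tsvq_tree(points: np.ndarray, weights: np.ndarray | None = None, seed: int = 0,
              n_restarts: int = 10) -> Dendrogram:
    """Divisive dendrogram by recursive weighted 2-means (TSVQ)."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 20 * n + 1000))
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 11])))
    counter = _Counter()
    root = _build_tsvq(X, w, np.arange(n), rng, n_restarts, np.inf, counter)
    return Dendrogram(root=root, n_leaves=n, leaf_ids=np.arange(n))


# ---------------------------------------------------------------------------
# Hybrid tree
# ---------------------------------------------------------------------------

def _renumber(node: _Node, counter: _Counter) -> None:
    node.order = counter.next()
    if not node.is_leaf:
        _renumber(node.left, counter)
        _renumber(node.right, counter)


def _cap_heights(node: _Node, cap: float) -> None:
    node.height = min(node.height, cap)
    if not node.is_leaf:
        _cap_heights(node.left, node.height)
        _cap_heights(node.right, node.height)


def hybrid_tree(points: np.ndarray, seed: int = 0, n_restarts: int = 10) -> Dendrogram:
    """Chipman-Tibshirani hybrid dendrogram on Euclidean distances.

    Every maximal mutual cluster appears as a contiguous subtree.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 20 * n + 1000))
    D = squareform(pdist(X))
    maximal = sorted(maximal_mutual_clusters(D), key=lambda s: min(s))
    if not maximal:
        return tsvq_tree(X, seed=seed, n_restarts=n_restarts)

    in_mc = np.full(n, -1)
    for mi, S in enumerate(maximal):
        for i in S:
            in_mc[i] = mi
    single_idx = np.nonzero(in_mc == -1)[0]
    reps = np.concatenate(
        [X[single_idx] if single_idx.size else np.empty((0, X.shape[1]))]
        + [X[sorted(S)].mean(axis=0, keepdims=True) for S in maximal]
    )
    rep_weight = np.concatenate([np.ones(single_idx.size), [len(S) for S in maximal]])
    # Map collapsed index -> original indices.
    rep_members = [np.array([i]) for i in single_idx] + [
        np.array(sorted(S)) for S in maximal
    ]

    seed_seq = np.random.SeedSequence([int(seed), 12])
    top_seed, *sub_seeds = seed_seq.generate_state(1 + len(maximal)).tolist()
    top = tsvq_tree(reps, weights=rep_weight, seed=top_seed, n_restarts=n_restarts)

    # Graft: rewrite leaf sets to original indices; expand mutual-cluster
    # leaves with their own TSVQ subtrees, heights capped at the graft point.
    def rewrite(node: _Node, parent_height: float) -> _Node:
        if node.is_leaf:
            members = rep_members[int(node.leaves[0])]
            if members.size == 1:
                node.leaves = members
                return node
            mi = int(in_mc[members[0]])
            sub = tsvq_tree(X[members], seed=sub_seeds[mi], n_restarts=n_restarts)
            _relabel_leaves(sub.root, members)
            _cap_heights(sub.root, parent_height)
            return sub.root
        node.leaves = np.concatenate(
            [np.atleast_1d(_collect(child)) for child in (node.left, node.right)]
        )
        return node

    def _collect(node: _Node) -> np.ndarray:
        if node.is_leaf:
            return rep_members[int(node.leaves[0])]
        return np.concatenate([_collect(node.left), _collect(node.right)])

    def walk(node: _Node, parent_height: float) -> _Node:
        new = rewrite(node, parent_height)
        if new is not node:
            return new  # grafted subtree, already finished
        if not node.is_leaf:
            node.left = walk(node.left, node.height)
            node.right = walk(node.right, node.height)
        return node

    root = walk(top.root, np.inf)
    _renumber(root, _Counter())
    return Dendrogram(root=root, n_leaves=n, leaf_ids=np.arange(n))


def _relabel_leaves(node: _Node, mapping: np.ndarray) -> None:
    node.leaves = mapping[node.leaves]
    if not node.is_leaf:
        _relabel_leaves(node.left, mapping)
        _relabel_leaves(node.right, mapping)


# ---------------------------------------------------------------------------
# Cutting and diagnostics
# ---------------------------------------------------------------------------

def cut_tree(tree: Dendrogram, k: int) -> Partition:
    """Partition into k clusters by removing the k-1 highest internal nodes.

    Ties in height break by node creation order (earlier-created nodes are
    removed first).  Cluster labels 1..k are assigned by each cluster's
    smallest member index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    frontier: list[_Node] = [tree.root]
    while len(frontier) < k:
        splittable = [nd for nd in frontier if not nd.is_leaf]
        if not splittable:
            break
        best = max(splittable, key=lambda nd: (nd.height, -nd.order))
        frontier.remove(best)
        frontier.extend([best.left, best.right])
    if len(frontier) != k:
        raise ValueError("tree cannot be cut into k clusters")
    clusters = sorted((sorted(int(i) for i in nd.leaves) for nd in frontier), key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return Partition(labels=labels, k=k)


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CH(k) = [between-SS / (k-1)] / [within-SS / (n-k)]."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k <= n-1 clusters")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in uniq:
        sub = X[labels == c]
        centroid = sub.mean(axis=0)
        between += sub.shape[0] * float(np.sum((centroid - grand) ** 2))
        within += float(np.sum((sub - centroid) ** 2))
    if within == 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def ch_profile(points: np.ndarray, tree: Dendrogram, k_range) -> dict:
    """CH values, percent change, and local extrema over cuts at each k."""
    ks = sorted(k_range)
    n = tree.n_leaves
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    ch = {}
    for k in ks:
        part = cut_tree(tree, k)
        ch[k] = calinski_harabasz(points, part.labels)
    pct = {
        ks[i]: 100.0 * (ch[ks[i + 1]] - ch[ks[i]]) / ch[ks[i]]
        for i in range(len(ks) - 1)
        if np.isfinite(ch[ks[i]]) and ch[ks[i]] != 0
    }
    extrema = {}
    for i in range(1, len(ks) - 1):
        prev_v, v, next_v = ch[ks[i - 1]], ch[ks[i]], ch[ks[i + 1]]
        if v > prev_v and v > next_v:
            extrema[ks[i]] = "maximum"
        elif v < prev_v and v < next_v:
            extrema[ks[i]] = "minimum"
    return {"ch": ch, "percent_change": pct, "extrema": extrema}


def silhouette(dist: np.ndarray, labels: np.ndarray) -> dict:
    """Silhouette coefficients: per subject, per cluster mean, and overall mean.

    s(i) = (b - a) / max(a, b), where a is the mean within-cluster distance
    excluding self and b is the smallest mean distance to another cluster.
    Singleton clusters get s = 0.
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    per_cluster = {int(c): float(s[labels == c].mean()) for c in uniq}
    return {"per_subject": s, "per_cluster": per_cluster, "mean": float(s.mean())}


def cluster_profiles(scores: np.ndarray, partition: Partition) -> list[ClusterProfile]:
    """Per-cluster factor-score means with Cohen's d vs the whole sample."""
    X = np.asarray(scores, dtype=float)
    labels = partition.labels
    grand_mean = X.mean(axis=0)
    grand_sd = X.std(axis=0, ddof=1)
    grand_sd = np.where(grand_sd == 0, 1.0, grand_sd)
    out = []
    n = X.shape[0]
    for c in range(1, partition.k + 1):
        sel = labels == c
        means = X[sel].mean(axis=0)
        d = (means - grand_mean) / grand_sd
        out.append(
            ClusterProfile(
                cluster=c,
                size=int(sel.sum()),
                share=float(sel.sum() / n),
                factor_means=means,
                cohens_d=d,
                stars=[d_stars(v) for v in d],
            )
        )
    return out
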