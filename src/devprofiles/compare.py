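"""Fowlkes-Mallows comparison of two clusterings with a permutation null.

B = T / sqrt(P * Q), where from the k_a x k_b contingency table M of the two
partitions T = sum(m_ij^2) - n, P = sum(row sums^2) - n, Q = sum(col sums^2) - n.
The null distribution comes from random permutations of the first partition's
subject-to-cluster assignment, which for a fixed dendrogram cut is the same as
permuting the subject-to-leaf assignment of that dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Dendrogram, Partition, cut_tree


@dataclass
class FMResult:
    b_index: float
    k_a: int
    k_b: int
    null_mean: float
    null_var: float
    n_permutations: int
    p_value: float
    seed: int
    null_sample: np.ndarray | None = None


def _pair_terms(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[float, float, float]:
    a_codes = np.unique(labels_a, return_inverse=True)[1]
    b_codes = np.unique(labels_b, return_inverse=True)[1]
    ka, kb = a_codes.max() + 1, b_codes.max() + 1
    n = a_codes.size
    M = np.bincount(a_codes * kb + b_codes, minlength=ka * kb).reshape(ka, kb).astype(float)
    T = float(np.sum(M**2) - n)
    P = float(np.sum(M.sum(axis=1) ** 2) - n)
    Q = float(np.sum(M.sum(axis=0) ** 2) - n)
    return T, P, Q


def fowlkes_mallows(part_a, part_b) -> float:
    """Fowlkes-Mallows index of two partitions over the same subjects."""
    la = part_a.labels if isinstance(part_a, Partition) else np.asarray(part_a)
    lb = part_b.labels if isinstance(part_b, Partition) else np.asarray(part_b)
    if la.size != lb.size or la.size == 0:
        raise ValueError("partitions must cover the same non-empty subject set")
    T, P, Q = _pair_terms(la, lb)
    if T == 0.0:
        return 0.0
    return T / np.sqrt(P * Q)


def fm_expected_null(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Closed-form expectation of B under random label permutation."""
    _, P, Q = _pair_terms(np.asarray(labels_a), np.asarray(labels_b))
    n = np.asarray(labels_a).size
    return float(np.sqrt(P * Q) / (n * (n - 1)))


def fm_permutation_test(
    tree_a: Dendrogram | np.ndarray,
    k_a: int,
    tree_b: Dendrogram | np.ndarray,
    k_b: int,
    n_perm: int = 1000,
    seed: int = 0,
    keep_null: bool = False,
) -> FMResult:
    """Two-sided permutation test of the Fowlkes-Mallows index.

    ``tree_a``/``tree_b`` may be dendrograms (cut at ``k_a``/``k_b``) or label
    vectors (used as-is).  p uses the add-one correction
    ``2 * min(r_low, r_high) / (n_perm + 1)`` capped at 1, where the counts
    include the observed statistic.
    """
    la = cut_tree(tree_a, k_a).labels if isinstance(tree_a, Dendrogram) else np.asarray(tree_a)
    lb = cut_tree(tree_b, k_b).labels if isinstance(tree_b, Dendrogram) else np.asarray(tree_b)
    if la.size < 10:
        raise ValueError("need at least 10 shared subjects")
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    observed = fowlkes_mallows(la, lb)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 21])))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = fowlkes_mallows(rng.permutation(la), lb)
    r_low = 1 + int(np.sum(null <= observed))
    r_high = 1 + int(np.sum(null >= observed))
    p = min(1.0, 2.0 * min(r_low, r_high) / (n_perm + 1))
    return FMResult(
        b_index=float(observed),
        k_a=int(k_a),
        k_b=int(k_b),
        null_mean=float(null.mean()),
        null_var=float(null.var(ddof=1)),
        n_permutations=n_perm,
        p_value=float(p),
        seed=seed,
        null_sample=null if keep_null else None,
    )
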