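"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible from the defining
formulas — explicit loops over clusters, pairs and trees — and stays
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_contingency(a, b):
    a, b = list(a), list(b)
    ca, cb = sorted(set(a)), sorted(set(b))
    table = [[0] * len(cb) for _ in ca]
    for x, y in zip(a, b):
        table[ca.index(x)][cb.index(y)] += 1
    return np.array(table)


def brute_nmi(a, b) -> float:
    """MI / mean entropy, summing the contingency table term by term."""
    table = brute_contingency(a, b)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i][j]
            if nij > 0:
                mi += nij / n * math.log(nij * n / (rows[i] * cols[j]))
    h_a = -sum(r / n * math.log(r / n) for r in rows if r > 0)
    h_b = -sum(c / n * math.log(c / n) for c in cols if c > 0)
    if h_a == 0 and h_b == 0:
        return 1.0
    return mi / ((h_a + h_b) / 2)


def brute_ari(a, b) -> float:
    """Pair enumeration over all C(n,2) pairs, then chance adjustment."""
    a, b = list(a), list(b)
    n = len(a)
    together_both = together_a = together_b = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        together_a += sa
        together_b += sb
        together_both += sa and sb
    total_pairs = n * (n - 1) / 2
    expected = together_a * together_b / total_pairs
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def brute_purity(p, truth) -> float:
    p, truth = list(p), list(truth)
    correct = 0
    for c in set(p):
        members = [truth[i] for i in range(len(p)) if p[i] == c]
        correct += max(members.count(t) for t in set(members))
    return correct / len(p)


def brute_diversity(members) -> float:
    m = len(members)
    total = 0.0
    for i in range(m - 1):
        for j in range(i + 1, m):
            total += 1 - brute_nmi(members[i], members[j])
    return 2 * total / (m * (m - 1))


def brute_quality(members, truth) -> float:
    return sum(brute_nmi(p, truth) for p in members) / len(members)


def brute_coassociation(members) -> np.ndarray:
    n = len(members[0])
    co = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            co[i, j] = sum(1 for p in members if p[i] == p[j]) / len(members)
    return co


def brute_proximity(per_tree_leaves) -> np.ndarray:
    """Share-a-leaf fractions from an (N, ntrees) leaf-index matrix."""
    leaves = np.asarray(per_tree_leaves)
    n, ntrees = leaves.shape
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = sum(1 for t in range(ntrees) if leaves[i, t] == leaves[j, t]) / ntrees
    return s


def brute_ward_labels(dist: np.ndarray, k: int) -> np.ndarray:
    """Naive Ward agglomeration (squared-distance Lance–Williams update).

    Scans all active cluster pairs each step, merges the closest, and
    updates squared inter-cluster distances with the Ward recursion.
    Returns 0-based flat labels at k clusters.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    clusters = {i: [i] for i in range(n)}
    d2 = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > k:
        (ci, cj), _ = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = len(clusters[ci]), len(clusters[cj])
        merged = clusters.pop(ci) + clusters.pop(cj)
        new_d2 = {}
        for ck, members in clusters.items():
            nk = len(members)
            dik = d2[tuple(sorted((ci, ck)))]
            djk = d2[tuple(sorted((cj, ck)))]
            dij = d2[tuple(sorted((ci, cj)))]
            val = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            new_d2[tuple(sorted((ck, next_id)))] = val
        d2 = {
            pair: v
            for pair, v in d2.items()
            if ci not in pair and cj not in pair
        }
        d2.update(new_d2)
        clusters[next_id] = merged
        next_id += 1
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(clusters.values(), key=min)):
        for m in members:
            labels[m] = lab
    return labels


def brute_best_two_partition(points: np.ndarray):
    """Exhaustive minimum within-cluster sum of squares over 2-partitions."""
    n = len(points)
    best, best_cost = None, np.inf
    for mask in range(1, 2 ** (n - 1)):
        labels = np.array([(mask >> i) & 1 for i in range(n)])
        cost = 0.0
        for c in (0, 1):
            grp = points[labels == c]
            if len(grp):
                cost += ((grp - grp.mean(axis=0)) ** 2).sum()
        if cost < best_cost:
            best, best_cost = labels, cost
    return best, best_cost
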