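"""Independent brute-force oracles used across the test suite.

These deliberately recompute quantities from first principles (direct
formulas, exhaustive enumeration) rather than reusing any code path from
the package.
"""

from __future__ import annotations

import itertools
from itertools import combinations

import numpy as np


def naive_ward_merges(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) Ward: recompute the ESS-based merge cost of every cluster
    pair from the original squared distances at every step.

    cost(A, B) = 2 * [ESS(A u B) - ESS(A) - ESS(B)],
    ESS(C) = (1/|C|) * sum_{i<j in C} d_ij^2; merge height = sqrt(cost).
    """
    n = d.shape[0]
    d2 = d**2

    def ess(c: frozenset) -> float:
        members = sorted(c)
        return sum(d2[a, b] for a, b in combinations(members, 2)) / len(members)

    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cost = 2.0 * (
                    ess(clusters[i] | clusters[j])
                    - ess(clusters[i])
                    - ess(clusters[j])
                )
                if cost < best_cost - 1e-12:
                    best_cost, best = cost, (i, j)
        i, j = best
        merges.append((clusters[i], clusters[j], float(np.sqrt(best_cost))))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def permanova_f_direct(d: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F straight from the partition-of-sums definition."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(
        d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in combinations(members, 2)
        ) / len(members)
    if ss_within == 0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact p over every distinct relabeling (identity included)."""
    obs = permanova_f_direct(d, labels)
    seen = sorted(set(itertools.permutations(labels.tolist())))
    count = sum(
        1 for lab in seen if permanova_f_direct(d, np.array(lab)) >= obs
    )
    return count / len(seen)


def merge_leaf_sets(tree) -> list[tuple[frozenset, frozenset, float]]:
    """Convert a ClusterTree's merges to (left leaf set, right leaf set, h)."""
    n = tree.n_leaves
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h) in enumerate(tree.merges):
        sets[n + k] = sets[a] | sets[b]
        out.append((sets[a], sets[b], h))
    return out
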