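"""Co-abundance group (guild/CAG) detection.

The SparCC correlation matrix is turned into a dissimilarity (1 - r),
clustered with Ward's criterion, and the resulting tree is cut from the
top down by PERMANOVA: at each internal node the two child clusters are
compared on the corresponding sub-distance-matrix, and a node whose
children are not significantly separated (p above the stop level) becomes
a single CAG. Member relative abundances are then summed per CAG, and the
display network keeps only edges with |r| at or above a threshold.

PERMANOVA here follows the classical partition of squared dissimilarities:

    SS_total   = (1/N) sum_{i<j} d_ij^2
    SS_within  = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F   = [ (SS_total - SS_within) / (a - 1) ] / [ SS_within / (N - a) ]

with significance from random label permutations (add-one corrected) or,
for small problems, exhaustive enumeration of all distinct labelings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClusterTree,
    CorrelationMatrix,
    DistanceMatrix,
    GuildAbundanceTable,
    GuildAssignment,
    RelativeAbundanceTable,
    SampleMetadata,
)

__all__ = [
    "PermanovaResult",
    "to_distance",
    "ward_linkage",
    "permanova",
    "cut_tree_by_permanova",
    "guild_abundance",
    "guild_summary",
    "build_network",
]

DEFAULT_EDGE_THRESHOLD = 0.6
DEFAULT_CUT_ALPHA = 0.001
DEFAULT_CUT_PERMUTATIONS = 999


def to_distance(corr: CorrelationMatrix) -> DistanceMatrix:
    """Dissimilarity d = 1 - r, ranging over [0, 2]."""
    return DistanceMatrix(list(corr.ids), 1.0 - corr.r)


def ward_linkage(dist: DistanceMatrix, dialect: str = "ward.D2") -> ClusterTree:
    """Agglomerative Ward clustering via Lance-Williams updates.

    ``ward.D2`` (default) runs the recursion on squared dissimilarities and
    reports heights on the original scale — the textbook Ward criterion,
    identical to scipy's ``linkage(..., 'ward')``. ``ward.D`` applies the
    same recursion to the raw dissimilarities (R hclust's legacy variant),
    for sensitivity checks. Ties are broken by the lexicographically
    smallest (node id, node id) pair, so output is deterministic in input
    order. O(n^3), fine for the few hundred ASVs a prevalence-filtered
    table contains.
    """
    if dialect not in ("ward.D2", "ward.D"):
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    n = len(dist.ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 items")
    total = 2 * n - 1
    S = np.full((total, total), np.inf)
    S[:n, :n] = dist.d ** 2 if dialect == "ward.D2" else dist.d
    sizes = np.ones(total)
    active: list[int] = list(range(n))  # kept sorted ascending
    merges: list[tuple[int, int, float]] = []
    for k in range(n - 1):
        sub = S[np.ix_(active, active)].copy()
        sub[np.tril_indices(len(active))] = np.inf
        flat = int(np.argmin(sub))  # row-major: lexicographically first minimum
        ai, aj = divmod(flat, len(active))
        a, b = active[ai], active[aj]
        cost = S[a, b]
        height = float(np.sqrt(cost)) if dialect == "ward.D2" else float(cost)
        new = n + k
        sizes[new] = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            upd = (
                (sizes[a] + sizes[c]) * S[a, c]
                + (sizes[b] + sizes[c]) * S[b, c]
                - sizes[c] * cost
            ) / (sizes[a] + sizes[b] + sizes[c])
            S[new, c] = S[c, new] = upd
        active.remove(a)
        active.remove(b)
        active.append(new)
        merges.append((a, b, height))
    return ClusterTree(list(dist.ids), merges)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    method: str = "permutation"

    def __post_init__(self) -> None:
        if not self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p-value below the permutation resolution")


def _pseudo_f_batch(D2: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of an integer label matrix (B x N).

    Every row must be a permutation of the same label multiset. Rows with
    zero within-group sum of squares (perfect separation) get F = +inf.
    """
    B, N = labels.shape
    codes = np.unique(labels[0])
    a = len(codes)
    sizes = np.array([(labels[0] == c).sum() for c in codes], dtype=float)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = np.zeros(B)
    for c, n_g in zip(codes, sizes):
        Z = (labels == c).astype(float)
        ss_within += np.einsum("bi,bi->b", Z @ D2, Z) / (2.0 * n_g)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / (a - 1)) / (ss_within / (N - a))
    F[ss_within <= 1e-300] = np.inf
    return F


def _exhaustive_labelings(codes: np.ndarray, limit: int = 200_000) -> np.ndarray:
    counts = pd.Series(codes).value_counts()
    n_total = math.factorial(len(codes))
    for c in counts:
        n_total //= math.factorial(int(c))
    if n_total > limit:
        raise ValueError(
            f"{n_total} distinct labelings exceed the exhaustive limit; "
            "use the permutation method"
        )
    seen = sorted(set(itertools.permutations(codes.tolist())))
    return np.array(seen, dtype=codes.dtype)


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``grouping`` is one label per item, aligned with ``dist.ids``.
    ``method='permutation'`` draws ``n_perm`` random relabelings and
    reports the add-one-corrected p; ``method='exact'`` enumerates every
    distinct labeling (small problems only) for an exact p.
    """
    labels = np.asarray(list(grouping))
    if len(labels) != len(dist.ids):
        raise ValueError("grouping length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = {str(u): int((labels == u).sum()) for u in uniq}
    if max(sizes.values()) < 2:
        raise ValueError("at least one group must contain >= 2 items")
    D2 = dist.d.astype(float) ** 2
    observed = float(_pseudo_f_batch(D2, codes[None, :])[0])
    if method == "exact":
        all_labels = _exhaustive_labelings(codes)
        F_all = _pseudo_f_batch(D2, all_labels)
        # the identity labeling is one of the enumerated rows, so the count
        # of F >= observed is already add-one corrected
        p = float(np.sum(F_all >= observed)) / len(all_labels)
        n_eff = len(all_labels) - 1
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(codes, (n_perm, 1)), axis=1)
        F_perm = _pseudo_f_batch(D2, perms)
        p = (1.0 + float(np.sum(F_perm >= observed))) / (1.0 + n_perm)
        n_eff = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        pseudo_F=observed,
        p_value=p,
        n_permutations=n_eff,
        group_sizes=sizes,
        method=method,
    )


def _split_f_batch(
    D2: np.ndarray, sel_left: np.ndarray, sel_right: np.ndarray
) -> np.ndarray:
    """Two-group pseudo-F for batches of (left, right) leaf index sets.

    ``sel_left``/``sel_right`` are B x nL and B x nR index arrays into
    ``D2``; each row defines one two-group labeling over its own m-leaf
    subset, so the total sum of squares is recomputed per row.
    """
    B, nL = sel_left.shape
    nR = sel_right.shape[1]
    m = nL + nR
    N = D2.shape[0]
    ZL = np.zeros((B, N))
    ZR = np.zeros((B, N))
    np.put_along_axis(ZL, sel_left, 1.0, axis=1)
    np.put_along_axis(ZR, sel_right, 1.0, axis=1)
    GL = ZL @ D2
    wL = np.einsum("bi,bi->b", GL, ZL) / 2.0
    wR = np.einsum("bi,bi->b", ZR @ D2, ZR) / 2.0
    cross = np.einsum("bi,bi->b", GL, ZR)
    ss_total = (wL + wR + cross) / m
    ss_within = wL / nL + wR / nR
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_total - ss_within) / (ss_within / (m - 2))
    F[ss_within <= 1e-300] = np.inf
    return F


def cut_tree_by_permanova(
    tree: ClusterTree,
    dist: DistanceMatrix,
    alpha: float = DEFAULT_CUT_ALPHA,
    n_perm: int = DEFAULT_CUT_PERMUTATIONS,
    seed: int = 0,
    min_node_size: int = 2,
    permutation_scope: str = "tree",
) -> GuildAssignment:
    """Top-down recursive tree cut into CAGs.

    Depth-first from the root: each internal node's two child clusters are
    compared by two-group PERMANOVA. If p > alpha the node's whole leaf
    set becomes one CAG and descent stops (strict inequality: with 999
    permutations the minimum attainable p of 1/1000 equals 0.001 and does
    NOT stop at alpha = 0.001); otherwise both children are visited.
    Nodes with <= ``min_node_size`` leaves collapse untested — a 2-leaf
    node admits no informative two-group permutation.

    ``permutation_scope`` picks the null. ``'tree'`` (default) draws the
    two pseudo-clusters' members from ALL tree leaves: it asks whether
    these child clusters separate more than random same-size leaf sets of
    the whole community. ``'node'`` permutes labels over the node's own
    leaves only; because Ward already chose the most separated split of
    exactly those leaves, that null is anti-conservative and over-splits
    homogeneous clusters. At the root the two nulls coincide.

    Permutation streams are derived from (seed, node id) so the partition
    does not depend on traversal implementation details.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if permutation_scope not in ("tree", "node"):
        raise ValueError(f"unknown permutation_scope {permutation_scope!r}")
    if set(tree.leaves) != set(dist.ids):
        raise ValueError("tree leaves do not match the distance matrix ids")
    pos = {name: i for i, name in enumerate(dist.ids)}
    leaf_pos = np.array([pos[name] for name in tree.leaves])
    D2 = dist.d.astype(float) ** 2
    master = seed & 0x7FFFFFFF
    mapping: dict[str, str] = {}
    order: list[str] = []
    stack = [tree.root]
    n_leaves = tree.n_leaves
    while stack:
        node = stack.pop()
        leaf_idx = tree.leaf_indices(node)
        make_cag = False
        if node < n_leaves or len(leaf_idx) <= min_node_size:
            make_cag = True
        else:
            left, right = tree.children(node)
            Lpos = np.array([pos[tree.leaves[i]] for i in tree.leaf_indices(left)])
            Rpos = np.array([pos[tree.leaves[i]] for i in tree.leaf_indices(right)])
            nL, nR = len(Lpos), len(Rpos)
            obs = float(_split_f_batch(D2, Lpos[None, :], Rpos[None, :])[0])
            rng = np.random.default_rng(np.random.SeedSequence([master, node]))
            pool = leaf_pos if permutation_scope == "tree" else np.concatenate(
                [Lpos, Rpos]
            )
            n_exceed = 0
            for start in range(0, n_perm, 512):  # chunked to bound memory
                B = min(512, n_perm - start)
                draws = rng.permuted(np.tile(pool, (B, 1)), axis=1)
                F = _split_f_batch(D2, draws[:, :nL], draws[:, nL : nL + nR])
                n_exceed += int(np.sum(F >= obs))
            p = (1.0 + n_exceed) / (1.0 + n_perm)
            if p > alpha:
                make_cag = True
        if make_cag:
            label = f"CAG{len(order) + 1}"
            order.append(label)
            for i in leaf_idx:
                mapping[tree.leaves[i]] = label
        else:
            left, right = tree.children(node)
            stack.extend((right, left))  # visit left child first
    return GuildAssignment(mapping, order)


def guild_abundance(
    rel: RelativeAbundanceTable, assignment: GuildAssignment
) -> GuildAbundanceTable:
    """Sum member relative abundances per CAG, per sample."""
    missing = [a for a in assignment.asv_ids if a not in rel.df.columns]
    if missing:
        raise KeyError(f"assigned ASVs absent from the abundance table: {missing[:5]}")
    data = {
        label: rel.df[assignment.members(label)].sum(axis=1)
        for label in assignment.cag_order
    }
    return GuildAbundanceTable(pd.DataFrame(data, index=rel.df.index))


def guild_summary(
    guilds: GuildAbundanceTable, metadata: SampleMetadata
) -> pd.DataFrame:
    """Per-CAG mean relative abundance and coefficient of variation per
    group x timepoint (the bubble-plot quantities)."""
    meta = metadata.subset(guilds.sample_ids)
    rows = []
    for (group, tp), idx in meta.df.groupby(["group", "timepoint"]).groups.items():
        block = guilds.df.loc[list(idx)]
        means = block.mean(axis=0)
        sds = block.std(axis=0, ddof=1)
        for cag in guilds.cags:
            m = float(means[cag])
            cv = float(sds[cag] / m) if m > 0 else np.nan
            rows.append(
                {"cag": cag, "group": group, "timepoint": tp, "mean": m, "cv": cv}
            )
    return pd.DataFrame(rows)


def build_network(
    corr: CorrelationMatrix,
    assignment: GuildAssignment,
    rel: RelativeAbundanceTable,
    min_abs_r: float = DEFAULT_EDGE_THRESHOLD,
    pvalues: np.ndarray | None = None,
    taxonomy: dict[str, str] | None = None,
) -> nx.Graph:
    """Display network: one node per ASV, edges where |r| >= ``min_abs_r``.

    Node attributes: mean relative abundance, CAG label, optional taxonomy.
    Edge attributes: correlation, sign ('pos'/'neg'), weight = |r|, and the
    permutation p-value when supplied.
    """
    ids = list(corr.ids)
    mean_abund = rel.df.reindex(columns=ids).mean(axis=0)
    G = nx.Graph()
    for asv in ids:
        attrs = {
            "mean_relative_abundance": float(mean_abund.get(asv, np.nan)),
            "cag": assignment.mapping.get(asv, ""),
        }
        if taxonomy and asv in taxonomy:
            attrs["taxonomy"] = taxonomy[asv]
        G.add_node(asv, **attrs)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = float(corr.r[i, j])
            if abs(r) >= min_abs_r:
                attrs = {
                    "correlation": r,
                    "sign": "pos" if r >= 0 else "neg",
                    "weight": abs(r),
                }
                if pvalues is not None:
                    attrs["p_value"] = float(pvalues[i, j])
                G.add_edge(ids[i], ids[j], **attrs)
    return G
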