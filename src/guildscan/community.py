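"""Alpha/beta diversity and group-level community comparisons.

Shannon entropy is reported in bits (log base 2, the QIIME2 convention);
Bray-Curtis dissimilarity and classical PCoA cover beta diversity; groups
are compared per timepoint with Kruskal-Wallis (alpha diversity) and
pairwise PERMANOVA (community structure), each followed by
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal

from .datatypes import (
    DistanceMatrix,
    FeatureTable,
    RelativeAbundanceTable,
    SampleMetadata,
    require_same_samples,
)
from .guilds import permanova
from .stats import bh_adjust

__all__ = [
    "shannon",
    "observed_asvs",
    "alpha_diversity",
    "bray_curtis",
    "OrdinationResult",
    "pcoa",
    "groupwise_tests",
    "pairwise_permanova",
]


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of one sample's counts, in bits by default."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon entropy of an all-zero sample")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_asvs(counts) -> int:
    """Number of ASVs with a strictly positive count."""
    return int(np.sum(np.asarray(counts) > 0))


def alpha_diversity(table: FeatureTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon (bits) and observed-ASV richness."""
    return pd.DataFrame(
        {
            "shannon": [shannon(row, base) for row in table.counts],
            "observed_asvs": [observed_asvs(row) for row in table.counts],
        },
        index=table.sample_ids,
    )


def bray_curtis(table: FeatureTable | RelativeAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples."""
    vals = table.df.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need >= 2 samples for beta diversity")
    if np.any(vals.sum(axis=1) == 0):
        bad = list(table.df.index[vals.sum(axis=1) == 0])
        raise ValueError(f"zero-total samples have no Bray-Curtis distance: {bad}")
    return DistanceMatrix(list(table.df.index), squareform(pdist(vals, "braycurtis")))


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: pd.DataFrame  # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray  # all eigenvalues, descending, negatives included
    proportion_explained: np.ndarray  # per retained axis, vs positive-eig total


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical metric MDS (principal coordinates) of a distance matrix.

    The Gower matrix -1/2 J d^2 J is eigendecomposed; negative eigenvalues
    (non-Euclidean input) are reported, but coordinates are built from the
    positive ones only, with proportion explained taken against the
    positive-eigenvalue total.
    """
    d = dist.d
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[pos].sum()
    prop = eigvals[pos] / total if total > 0 else eigvals[pos]
    frame = pd.DataFrame(
        coords,
        index=dist.ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(list(dist.ids), frame, eigvals, prop)


def _kruskal_exact_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p for the Kruskal-Wallis H (small families only).

    H is monotone in sum_g R_g^2 / n_g for fixed pooled ranks (the tie
    correction is permutation-invariant), so enumeration compares that
    quantity directly.
    """
    import itertools

    from scipy.stats import rankdata as _rankdata

    values = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    ranks = _rankdata(values)

    def stat(perm) -> float:
        split, total = 0, 0.0
        for s in sizes:
            r = ranks[list(perm[split : split + s])]
            total += r.sum() ** 2 / s
            split += s
        return total

    obs = stat(range(len(values)))
    perms = list(itertools.permutations(range(len(values))))
    count = sum(1 for perm in perms if stat(perm) >= obs - 1e-9)
    return count / len(perms)


def groupwise_tests(
    alpha_table: pd.DataFrame,
    metadata: SampleMetadata,
    metrics: tuple[str, ...] = ("shannon", "observed_asvs"),
) -> pd.DataFrame:
    """Kruskal-Wallis across groups at each timepoint, BH-adjusted per metric.

    Timepoints with fewer than two groups are skipped (reported with NaN).
    """
    ids = require_same_samples(list(alpha_table.index), metadata.sample_ids)
    meta = metadata.subset(ids)
    rows = []
    for metric in metrics:
        for tp, idx in meta.df.groupby("timepoint").groups.items():
            sub = meta.df.loc[list(idx)]
            groups = [
                alpha_table.loc[list(g_idx), metric].to_numpy()
                for _, g_idx in sub.groupby("group").groups.items()
            ]
            if len(groups) < 2:
                rows.append(
                    {"metric": metric, "timepoint": tp, "H": np.nan, "p": np.nan}
                )
                continue
            if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups):
                h, p = 0.0, 1.0  # identical value multisets carry no signal
            elif sum(len(g) for g in groups) <= 8:
                h = kruskal(*groups).statistic
                p = _kruskal_exact_p(groups)  # chi-square approx unreliable here
            else:
                h, p = kruskal(*groups)
            rows.append({"metric": metric, "timepoint": tp, "H": h, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for metric in metrics:
        mask = (out["metric"] == metric) & out["p"].notna()
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def pairwise_permanova(
    dist: DistanceMatrix,
    metadata: SampleMetadata,
    n_perm: int = 9999,
    seed: int = 0,
    per_timepoint: bool = True,
) -> pd.DataFrame:
    """Pairwise group PERMANOVA on sample subsets, BH within each timepoint.

    Samples are the observations; for each timepoint every pair of groups
    is compared on the corresponding sub-distance-matrix.
    """
    meta = metadata.subset(dist.ids)
    rows = []
    tps = (
        meta.df.groupby("timepoint").groups.items()
        if per_timepoint
        else [("all", meta.df.index)]
    )
    counter = 0
    for tp, idx in tps:
        sub = meta.df.loc[list(idx)]
        groups = sorted(sub["group"].unique())
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pair_ids = list(
                    sub.index[sub["group"].isin([groups[i], groups[j]])]
                )
                if len(pair_ids) < 3:
                    continue
                res = permanova(
                    dist.submatrix(pair_ids),
                    sub.loc[pair_ids, "group"],
                    n_perm=n_perm,
                    seed=(seed + counter) & 0x7FFFFFFF,
                )
                counter += 1
                rows.append(
                    {
                        "timepoint": tp,
                        "group_a": groups[i],
                        "group_b": groups[j],
                        "pseudo_F": res.pseudo_F,
                        "p": res.p_value,
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = np.nan
        for tp in out["timepoint"].unique():
            mask = out["timepoint"] == tp
            out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
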