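"""CAG-phenotype association and differential CAG abundance.

Guild abundances are linked to continuous host phenotypes (hepatic
triglyceride, serum cholesterol, cecal SCFAs) by Spearman rank
correlation with BH FDR over the full CAG x variable family, and compared
between treatment groups with two-sided Mann-Whitney tests, BH-adjusted
per group pair. A Z-score table of group means supports heatmap-style
summaries.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr, rankdata

from .datatypes import (
    GuildAbundanceTable,
    PhenotypeTable,
    SampleMetadata,
    require_same_samples,
)
from .stats import bh_adjust

__all__ = [
    "spearman_assoc",
    "mann_whitney_da",
    "zscore_table",
    "spearman_exact_p",
]

_EXACT_N_MAX = 9


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9).

    Enumerates all n! orderings of one variable's ranks; p is the fraction
    with |rho| at least the observed |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > _EXACT_N_MAX:
        raise ValueError(f"exact enumeration limited to n <= {_EXACT_N_MAX}")
    rx = rankdata(x)
    ry = rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
    if denom == 0:
        return 1.0
    obs = abs(float((rx_c * ry_c).sum()) / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    rho_all = (rx_c[perms] * ry_c[None, :]).sum(axis=1) / denom
    return float(np.mean(np.abs(rho_all) >= obs - 1e-12))


def _spearman_one(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rho, p_t = spearmanr(x, y)
    if np.isnan(rho):
        return np.nan, np.nan
    if len(x) <= _EXACT_N_MAX:
        return float(rho), spearman_exact_p(x, y)
    return float(rho), float(p_t)


def spearman_assoc(
    guilds: GuildAbundanceTable,
    phen: PhenotypeTable,
    min_pairs: int = 3,
    intersect: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of every CAG against every phenotype.

    Missing phenotype values are handled pairwise-complete; cells with
    fewer than ``min_pairs`` complete pairs are marked untestable and
    excluded from the BH family (applied jointly over all testable
    CAG x variable cells).
    """
    ids = require_same_samples(guilds.sample_ids, phen.sample_ids, intersect=intersect)
    g = guilds.df.loc[ids]
    ph = phen.df.loc[ids]
    rows = []
    for cag in guilds.cags:
        for var in phen.variables:
            mask = ph[var].notna()
            n = int(mask.sum())
            if n < min_pairs:
                rows.append(
                    {"cag": cag, "variable": var, "rho": np.nan, "p": np.nan,
                     "n_pairs": n, "testable": False}
                )
                continue
            rho, p = _spearman_one(
                g.loc[mask, cag].to_numpy(), ph.loc[mask, var].to_numpy()
            )
            rows.append(
                {"cag": cag, "variable": var, "rho": rho, "p": p,
                 "n_pairs": n, "testable": not np.isnan(p)}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    mask = out["testable"]
    if mask.any():
        out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact when small and tie-free, else
    normal approximation with tie correction."""
    if np.array_equal(np.sort(x), np.sort(y)):
        return float(mannwhitneyu(x, y, method="asymptotic").statistic), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney_da(
    guilds: GuildAbundanceTable,
    metadata: SampleMetadata,
    pairs: list[tuple[str, str]] | None = None,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Differential CAG abundance between group pairs.

    BH is applied across CAGs within each group pair. ``direction`` names
    the group with the higher median (empty on ties).
    """
    meta = metadata.subset(guilds.sample_ids)
    if timepoint is not None:
        keep = meta.df["timepoint"] == timepoint
        meta = SampleMetadata(meta.df.loc[keep].copy())
    groups = sorted(meta.df["group"].unique())
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    rows = []
    for ga, gb in pairs:
        ids_a = list(meta.df.index[meta.df["group"] == ga])
        ids_b = list(meta.df.index[meta.df["group"] == gb])
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError(f"each group needs >= 2 samples ({ga} vs {gb})")
        for cag in guilds.cags:
            x = guilds.df.loc[ids_a, cag].to_numpy()
            y = guilds.df.loc[ids_b, cag].to_numpy()
            U, p = _mann_whitney(x, y)
            med_a, med_b = float(np.median(x)), float(np.median(y))
            direction = ga if med_a > med_b else (gb if med_b > med_a else "")
            rows.append(
                {"cag": cag, "group_a": ga, "group_b": gb, "U": U, "p": p,
                 "direction": direction}
            )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for ga, gb in pairs:
        mask = (out["group_a"] == ga) & (out["group_b"] == gb)
        out.loc[mask, "fdr"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def zscore_table(
    guilds: GuildAbundanceTable,
    metadata: SampleMetadata,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Z-scores of per-group mean CAG abundance (CAGs x groups).

    For each CAG, Z = (group mean - mean of group means) / SD of group
    means. A CAG with zero between-group SD gets Z = 0 for every group.
    """
    meta = metadata.subset(guilds.sample_ids)
    if timepoint is not None:
        keep = meta.df["timepoint"] == timepoint
        meta = SampleMetadata(meta.df.loc[keep].copy())
    groups = sorted(meta.df["group"].unique())
    if len(groups) < 2:
        raise ValueError("Z-scoring needs >= 2 groups")
    means = pd.DataFrame(
        {
            g: guilds.df.loc[meta.df.index[meta.df["group"] == g]].mean(axis=0)
            for g in groups
        }
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    z = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z
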