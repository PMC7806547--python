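"""Rarefaction, relative-abundance conversion and the prevalence filter.

The preprocessing mirrors a standard 16S workflow: samples are rarefied to
a common depth by subsampling reads without replacement (samples below the
depth are dropped and reported), and ASVs present in fewer than a given
fraction of samples are removed before correlation inference. The filter
report includes, per sample, the fraction of reads carried by the retained
ASVs — the statistic usually quoted to show the filtered set still covers
nearly all sequences.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, RelativeAbundanceTable

__all__ = [
    "PreprocessConfig",
    "RarefactionReport",
    "PrevalenceReport",
    "rarefy",
    "to_relative",
    "prevalence_filter",
]

DEFAULT_RAREFACTION_DEPTH = 16_500
DEFAULT_PREVALENCE = 0.2


@dataclass
class PreprocessConfig:
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    prevalence_threshold: float = DEFAULT_PREVALENCE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must be in (0, 1]")


@dataclass
class RarefactionReport:
    depth: int
    dropped_samples: list[str] = field(default_factory=list)
    dropped_totals: dict[str, int] = field(default_factory=dict)


@dataclass
class PrevalenceReport:
    threshold: float
    min_samples: int
    n_retained: int
    n_removed: int
    removed_asvs: list[str] = field(default_factory=list)
    # fraction of each sample's reads carried by the retained ASVs
    retained_read_fraction: pd.Series | None = None

    @property
    def mean_retained_pct(self) -> float:
        return float(self.retained_read_fraction.mean() * 100)

    @property
    def sd_retained_pct(self) -> float:
        return float(self.retained_read_fraction.std(ddof=1) * 100)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed on the id itself, so results do not depend
    # on sample order in the table
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])
    )


def rarefy(
    table: FeatureTable, depth: int, seed: int = 0
) -> tuple[FeatureTable, RarefactionReport]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample is drawn from a multivariate hypergeometric distribution over
    its reads. Samples with fewer than ``depth`` total reads are dropped and
    listed in the report. Zero counts stay zero.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.df.sum(axis=1)
    keep = totals >= depth
    report = RarefactionReport(
        depth=depth,
        dropped_samples=list(table.df.index[~keep]),
        dropped_totals={s: int(totals[s]) for s in table.df.index[~keep]},
    )
    out = np.zeros((int(keep.sum()), table.df.shape[1]), dtype=np.int64)
    kept_ids = list(table.df.index[keep])
    # draw in canonical (sorted ASV id) order so the result is equivariant
    # under column permutations of the input table
    order = np.argsort(np.asarray(table.df.columns, dtype=object))
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    for i, sid in enumerate(kept_ids):
        row = table.df.loc[sid].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            rng = _sample_rng(seed, sid)
            drawn = rng.multivariate_hypergeometric(
                row[order], depth, method="marginals"
            )
            out[i] = drawn[inverse]
    return (
        FeatureTable(pd.DataFrame(out, index=kept_ids, columns=table.df.columns)),
        report,
    )


def to_relative(table: FeatureTable) -> RelativeAbundanceTable:
    """Divide each sample row by its own total; rows sum to 1."""
    totals = table.df.sum(axis=1)
    if (totals == 0).any():
        bad = list(table.df.index[totals == 0])
        raise ValueError(f"all-zero samples cannot be normalized: {bad}")
    return RelativeAbundanceTable(table.df.div(totals, axis=0), closed=True)


def prevalence_filter(
    table: FeatureTable, threshold: float = DEFAULT_PREVALENCE
) -> tuple[FeatureTable, PrevalenceReport]:
    """Keep ASVs present (count > 0) in at least ``ceil(threshold * n)`` samples.

    "At least" is an inclusive bound: with 10 samples and threshold 0.2 an
    ASV present in exactly 2 samples is retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("prevalence threshold must be in (0, 1]")
    n = table.df.shape[0]
    min_samples = int(np.ceil(threshold * n))
    presence = (table.df > 0).sum(axis=0)
    keep = presence >= min_samples
    filtered = FeatureTable(table.df.loc[:, keep].copy())
    totals = table.df.sum(axis=1)
    retained = filtered.df.sum(axis=1)
    frac = (retained / totals.replace(0, np.nan)).fillna(0.0)
    report = PrevalenceReport(
        threshold=threshold,
        min_samples=min_samples,
        n_retained=int(keep.sum()),
        n_removed=int((~keep).sum()),
        removed_asvs=list(table.df.columns[~keep]),
        retained_read_fraction=frac,
    )
    return filtered, report
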