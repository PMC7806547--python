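"""Shared tabular and matrix containers for the guild-analysis pipeline.

Everything downstream operates on a small set of validated containers:
a count :class:`FeatureTable` (samples x ASVs), its relative-abundance
counterpart, sample metadata and phenotype tables keyed by ``sample_id``,
symmetric correlation/distance matrices over ASVs, a binary merge tree,
and a partition of ASVs into co-abundance groups (CAGs, "guilds").

All containers validate their invariants at construction and fail loudly
on malformed input rather than coercing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "RelativeAbundanceTable",
    "SampleMetadata",
    "PhenotypeTable",
    "CorrelationMatrix",
    "DistanceMatrix",
    "ClusterTree",
    "GuildAssignment",
    "require_same_samples",
]


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class FeatureTable:
    """Samples x ASVs table of non-negative integer read counts."""

    df: pd.DataFrame  # index = sample_ids, columns = asv_ids, int counts

    def __post_init__(self) -> None:
        if not isinstance(self.df, pd.DataFrame):
            raise TypeError("FeatureTable wraps a pandas DataFrame")
        _check_unique(self.df.index, "sample ids")
        _check_unique(self.df.columns, "ASV ids")
        vals = self.df.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise ValueError("non-numeric counts in feature table")
        if vals.size:
            if np.any(vals < 0):
                r, c = np.argwhere(vals < 0)[0]
                raise ValueError(
                    f"negative count at sample {self.df.index[r]!r}, "
                    f"ASV {self.df.columns[c]!r}"
                )
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                r, c = np.argwhere(np.mod(vals, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {self.df.index[r]!r}, "
                    f"ASV {self.df.columns[c]!r}"
                )
        self.df = self.df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def require_min_size(self, n_samples: int = 2, n_asvs: int = 2) -> None:
        if self.df.shape[0] < n_samples or self.df.shape[1] < n_asvs:
            raise ValueError(
                f"need at least {n_samples} samples and {n_asvs} ASVs, "
                f"got shape {self.df.shape}"
            )


@dataclass
class RelativeAbundanceTable:
    """Samples x ASVs fractions.

    ``closed`` tables have rows summing to 1; tables produced against a
    pre-filter total (a subset of ASVs) may sum to less and carry
    ``closed=False``.
    """

    df: pd.DataFrame
    closed: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample ids")
        _check_unique(self.df.columns, "ASV ids")
        vals = self.df.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = vals.sum(axis=1)
        if self.closed:
            if vals.size and not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.df.index[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"sample {bad!r} does not sum to 1")
        elif vals.size and np.any(sums > 1.0 + 1e-9):
            raise ValueError("open relative abundances must sum to <= 1")
        self.df = self.df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()


@dataclass
class SampleMetadata:
    """Per-sample categorical descriptors: group, timepoint, optional cage."""

    df: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample ids")
        for col in ("group", "timepoint"):
            if col not in self.df.columns:
                raise ValueError(f"metadata is missing required column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    @property
    def timepoints(self) -> pd.Series:
        return self.df["timepoint"]

    def subset(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise KeyError(f"samples absent from metadata: {missing[:5]}")
        return SampleMetadata(self.df.loc[list(sample_ids)].copy())


@dataclass
class PhenotypeTable:
    """Per-sample continuous host variables (TG, TC, SCFAs, ...).

    Missing values are NaN; each variable needs >= 3 non-missing values to
    enter association testing.
    """

    df: pd.DataFrame  # index = sample_id, float columns, NaN = missing

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample ids")
        self.df = self.df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    def testable_variables(self, min_n: int = 3) -> list[str]:
        return [v for v in self.df.columns if self.df[v].notna().sum() >= min_n]


def _check_square(ids, m: np.ndarray, what: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    n = len(ids)
    if m.shape != (n, n):
        raise ValueError(f"{what} must be {n}x{n}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    return (m + m.T) / 2.0


@dataclass
class CorrelationMatrix:
    """Symmetric ASV x ASV basis-correlation estimates in [-1, 1]."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "ids")
        self.r = _check_square(self.ids, self.r, "correlation matrix")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be 1")
        if np.any(self.r < -1 - 1e-9) or np.any(self.r > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        np.clip(self.r, -1.0, 1.0, out=self.r)
        np.fill_diagonal(self.r, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "ids")
        self.d = _check_square(self.ids, self.d, "distance matrix")
        if np.any(self.d < -1e-12):
            raise ValueError("distances must be non-negative")
        np.clip(self.d, 0.0, None, out=self.d)
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("distance diagonal must be 0")
        np.fill_diagonal(self.d, 0.0)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class ClusterTree:
    """Full binary agglomerative merge tree over ASVs.

    Leaves are numbered ``0 .. n-1`` in the order of ``leaves``; the i-th
    merge creates internal node ``n + i`` from two existing node ids.
    Heights are non-decreasing in merge order (Ward is reducible, so no
    inversions occur).
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        self.leaves = _check_unique(self.leaves, "leaf ids")
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"a full binary tree over {n} leaves needs {n - 1} merges")
        used: set[int] = set()
        prev_h = -np.inf
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            for child in (a, b):
                if not 0 <= child < node:
                    raise ValueError(f"merge {k} references unknown node {child}")
                if child in used:
                    raise ValueError(f"node {child} merged twice")
                used.add(child)
            if h < prev_h - 1e-9:
                raise ValueError("merge heights must be non-decreasing")
            prev_h = max(prev_h, h)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * len(self.leaves) - 2 if len(self.leaves) > 1 else 0

    def children(self, node: int) -> tuple[int, int]:
        n = len(self.leaves)
        if node < n:
            raise ValueError(f"leaf {node} has no children")
        a, b, _ = self.merges[node - n]
        return a, b

    def height(self, node: int) -> float:
        n = len(self.leaves)
        return 0.0 if node < n else self.merges[node - n][2]

    def leaf_indices(self, node: int) -> list[int]:
        """Leaf indices under ``node``, in left-to-right tree order."""
        n = len(self.leaves)
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b = self.children(v)
                stack.extend((b, a))
        return out

    def leaf_names(self, node: int) -> list[str]:
        return [self.leaves[i] for i in self.leaf_indices(node)]

    def to_linkage(self) -> np.ndarray:
        """Return a scipy-style ``(n-1) x 4`` linkage matrix."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            sizes[n + k] = sizes[a] + sizes[b]
            Z[k] = [a, b, h, sizes[n + k]]
        return Z

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - self.height(node)
            if node < len(self.leaves):
                return f"{self.leaves[node]}:{bl:.10g}"
            a, b = self.children(node)
            h = self.height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        if len(self.leaves) == 1:
            return f"{self.leaves[0]}:0;"
        root = self.root
        a, b = self.children(root)
        h = self.height(root)
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class GuildAssignment:
    """Partition of ASVs into CAGs; labels ordered by discovery."""

    mapping: dict[str, str]
    cag_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty guild assignment")
        seen: list[str] = []
        for label in self.mapping.values():
            if label not in seen:
                seen.append(label)
        if not self.cag_order:
            self.cag_order = seen
        if set(self.cag_order) != set(seen):
            raise ValueError("cag_order inconsistent with mapping labels")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.mapping)

    @property
    def n_cags(self) -> int:
        return len(self.cag_order)

    def members(self, label: str) -> list[str]:
        return [a for a, c in self.mapping.items() if c == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"asv_id": list(self.mapping), "cag": list(self.mapping.values())}
        ).set_index("asv_id")

    def labels_for(self, asv_ids) -> list[str]:
        return [self.mapping[a] for a in asv_ids]


@dataclass
class GuildAbundanceTable:
    """Samples x CAGs matrix of summed member relative abundances.

    Row totals equal the summed relative abundance of all clustered ASVs in
    that sample, hence are <= 1.
    """

    df: pd.DataFrame  # index = sample_id, columns = CAG labels

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "sample ids")
        _check_unique(self.df.columns, "CAG labels")
        vals = self.df.to_numpy(dtype=float)
        if np.any(vals < -1e-12):
            raise ValueError("guild abundances must be non-negative")
        if vals.size and np.any(vals.sum(axis=1) > 1.0 + 1e-9):
            raise ValueError("guild abundances cannot sum above 1 in a sample")
        self.df = self.df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def cags(self) -> list[str]:
        return list(self.df.columns)


def require_same_samples(left_ids, right_ids, *, intersect: bool = False) -> list[str]:
    """Check that two sample-id sets match; optionally intersect explicitly.

    Joins between tables must never silently drop samples — mismatches are
    an error unless the caller opts into the intersection.
    """
    left, right = set(left_ids), set(right_ids)
    if left == right:
        return [s for s in left_ids if s in right]
    if intersect:
        return [s for s in left_ids if s in right]
    only_l = sorted(left - right)[:5]
    only_r = sorted(right - left)[:5]
    raise ValueError(
        "sample sets differ between tables "
        f"(only in first: {only_l}, only in second: {only_r}); "
        "pass intersect=True to join on the overlap"
    )
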