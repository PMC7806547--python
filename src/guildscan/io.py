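"""Readers and writers for the plain-text formats the pipeline touches.

Feature tables, metadata and phenotypes are UTF-8 TSV; QIIME2-style
BIOM-TSV headers (``# Constructed from biom file`` / ``#OTU ID`` /
``#ASV ID``) are tolerated. Networks are written as GraphML, Cytoscape
SIF, or an edge-list TSV; cluster trees as Newick.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClusterTree,
    CorrelationMatrix,
    DistanceMatrix,
    FeatureTable,
    PhenotypeTable,
    SampleMetadata,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "read_phenotypes",
    "write_network",
    "read_network_graphml",
    "write_tree_newick",
    "write_square_matrix",
    "read_square_matrix",
]

_MISSING = ("NA", "")


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV with one header row and a leading id column.

    '#' is not a comment character inside data; only leading BIOM-style
    banner lines are stripped.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    # strip BIOM banner ("# Constructed from biom file") but keep the
    # "#OTU ID"/"#ASV ID" header line, minus its leading '#'
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        head = lines[start].lstrip("#").strip().lower()
        if head.startswith(("otu id", "asv id", "feature id", "sample id", "sample-id")):
            lines[start] = lines[start].lstrip("#")
            break
        start += 1
    if start >= len(lines):
        raise ValueError(f"{path}: no header row found")
    from io import StringIO

    df = pd.read_csv(
        StringIO("\n".join(lines[start:])),
        sep="\t",
        header=0,
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment=None,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_feature_table(
    path: str | os.PathLike, orientation: str = "asvs-as-rows"
) -> FeatureTable:
    """Read an ASV count table.

    ``orientation='asvs-as-rows'`` (the QIIME2 export convention, default)
    transposes on read so that the returned table is samples x ASVs.
    Non-integer or negative cells raise with the offending row/column named.
    """
    if orientation not in ("samples-as-rows", "asvs-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = _read_tsv(path)
    num = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        num[col] = converted
    if orientation == "asvs-as-rows":
        num = num.T
    bad = (num.to_numpy() < 0) | (np.mod(num.to_numpy(), 1) != 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid count {num.iat[r, c]!r} at sample "
            f"{num.index[r]!r}, ASV {num.columns[c]!r}"
        )
    return FeatureTable(num)


def write_feature_table(
    table: FeatureTable, path: str | os.PathLike, orientation: str = "asvs-as-rows"
) -> None:
    df = table.df.T if orientation == "asvs-as-rows" else table.df
    label = "asv_id" if orientation == "asvs-as-rows" else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    """Read sample metadata (sample_id, group, timepoint, optional cage...).

    Unknown columns are preserved as-is.
    """
    df = _read_tsv_with_id(path)
    return SampleMetadata(df)


def _read_tsv_with_id(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    id_aliases = {"sample_id", "sample-id", "sampleid", "#sampleid", "#sample id"}
    if not header or header[0].strip().lower() not in id_aliases:
        raise ValueError(
            f"{path}: first column must be sample_id, got {header[0]!r}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    """Read per-sample continuous phenotypes; 'NA' or empty cells are missing."""
    raw = _read_tsv_with_id(path)
    out = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = raw[col].where(~raw[col].isin(_MISSING), other=np.nan)
        out[col] = pd.to_numeric(vals, errors="raise")
    return PhenotypeTable(out)


def write_network(graph: nx.Graph, path: str | os.PathLike, format: str = "graphml") -> None:
    """Write a co-abundance network in a Cytoscape-importable format.

    ``graphml`` round-trips all node/edge attributes; ``sif`` uses the
    interaction labels ``pos``/``neg``; ``edge-tsv`` is a flat edge list.
    """
    if format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            written = set()
            for u, v, attrs in graph.edges(data=True):
                fh.write(f"{u}\t{attrs.get('sign', 'pos')}\t{v}\n")
                written.update((u, v))
            for node in graph.nodes:
                if node not in written:
                    fh.write(f"{node}\n")
    elif format == "edge-tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "correlation": attrs.get("correlation", np.nan),
                "sign": attrs.get("sign", ""),
            }
            for u, v, attrs in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "correlation", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(path)


def write_tree_newick(tree: ClusterTree, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def write_square_matrix(
    mat: CorrelationMatrix | DistanceMatrix, path: str | os.PathLike
) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="id")


def read_square_matrix(path: str | os.PathLike, kind: str = "correlation"):
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if kind == "correlation":
        return CorrelationMatrix(ids, df.to_numpy(dtype=float))
    if kind == "distance":
        return DistanceMatrix(ids, df.to_numpy(dtype=float))
    raise ValueError(f"unknown matrix kind {kind!r}")
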