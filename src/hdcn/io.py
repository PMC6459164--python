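"""TSV readers and writers for every external table.

All tables are tab-delimited UTF-8 with a header row. Reader/writer pairs
are lossless round trips for valid inputs.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from hdcn._log import get_logger
from hdcn.containers import (
    COMPARTMENTS,
    ClonotypeTable,
    ExpressionMatrix,
    LocalizationAnnotation,
)

log = get_logger("hdcn.io")


def read_expression_matrix(path, group_table_path) -> ExpressionMatrix:
    """Read a gene x sample expression TSV plus its sample-group table.

    The matrix file has a header row of sample ids and gene ids in the first
    column; the group table has columns ``sample_id`` and ``group``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[
                pd.to_numeric(df[col], errors="coerce").isna()
            ]
            gene = bad[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value for gene {gene!r}, sample {col!r} in {path}"
            )
    groups_df = pd.read_csv(group_table_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(groups_df.columns):
        raise ValueError(
            f"group table {group_table_path} must have columns sample_id, group"
        )
    groups_all = dict(zip(groups_df["sample_id"], groups_df["group"]))
    missing = [s for s in df.columns if s not in groups_all]
    if missing:
        raise ValueError(f"samples absent from group table: {missing}")
    return ExpressionMatrix(df.astype(float), {s: groups_all[s] for s in df.columns})


def write_expression_matrix(matrix: ExpressionMatrix, path, group_table_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": [matrix.groups[s] for s in matrix.sample_ids]}
    ).to_csv(group_table_path, sep="\t", index=False)


def read_clonotype_table(path) -> ClonotypeTable:
    """Read a clonotype TSV (sample_id, v_gene, j_gene, junction_nt, count)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "v_gene": str, "j_gene": str, "junction_nt": str},
    )
    if "count" in df.columns and not np.issubdtype(df["count"].dtype, np.integer):
        raise ValueError(f"non-integer counts in {path}")
    return ClonotypeTable(df)


def write_clonotype_table(table: ClonotypeTable, path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_network_and_annotations(
    edges_path, annotations_path
) -> tuple[nx.Graph, LocalizationAnnotation]:
    """Read an undirected edge list and a protein->compartment table.

    Self-loop rows are dropped with a warning; duplicate and reversed edges
    are merged. An annotation using a compartment outside the 10-label
    vocabulary is a hard error.
    """
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    if edges.shape[1] < 2:
        raise ValueError(f"edge list {edges_path} needs two columns")
    a, b = edges.columns[:2]
    graph = nx.Graph()
    n_loops = 0
    for u, v in zip(edges[a], edges[b]):
        if u == v:
            n_loops += 1
            continue
        graph.add_edge(u, v)
    if n_loops:
        log.warning("dropped %d self-loop edge rows from %s", n_loops, edges_path)
    ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if not {"protein", "compartment"} <= set(ann.columns):
        raise ValueError(
            f"annotation table {annotations_path} needs columns protein, compartment"
        )
    mapping = dict(zip(ann["protein"], ann["compartment"]))
    return graph, LocalizationAnnotation(mapping)


def write_network(graph: nx.Graph, path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotations(annotations: LocalizationAnnotation, path) -> None:
    pd.DataFrame(
        sorted(annotations.mapping.items()), columns=["protein", "compartment"]
    ).to_csv(path, sep="\t", index=False)


def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file (one pair per line).

    Blank lines and lines starting with ``#`` are ignored. Keys mirror CLI
    flags with dashes replaced by underscores.
    """
    config: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


def write_config(config: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in config.items())
    )


__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clonotype_table",
    "write_clonotype_table",
    "read_network_and_annotations",
    "write_network",
    "write_annotations",
    "read_config",
    "write_config",
    "COMPARTMENTS",
]
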