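"""Plain-text I/O: expression/phenotype TSV, edge lists, GraphML, JSON.

Expression files are genes-by-samples TSV with a header row of sample ids
and a first column of gene ids.  All floats are written with 10 significant
digits so that write -> read round-trips are lossless at that precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .ggm import EdgeSet
from .network import GeneNetwork
from .synthetic import ExpressionMatrix, PhenotypeVector

__all__ = [
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "write_edge_list",
    "write_graphml",
    "write_node_table",
    "write_json",
]

_FMT = "{:.10g}"


def _parse_float(cell: str, path: str, lineno: int) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: non-numeric cell {cell!r}"
        ) from None
    if math.isnan(value):
        raise ValueError(f"{path}:{lineno}: missing value (NaN) not allowed")
    return value


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV expression matrix.

    Raises with the offending line number on duplicate gene ids, ragged
    rows, or non-numeric cells.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}:1: duplicate sample ids in header")
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(cells) - 1} values, "
                f"expected {len(sample_ids)})"
            )
        gid = cells[0]
        if gid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)
        rows.append([_parse_float(c, str(path), lineno) for c in cells[1:]])
    return ExpressionMatrix(values=rows, gene_ids=gene_ids, sample_ids=sample_ids)


def write_expression(X: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(X.sample_ids) + "\n")
        for gid, row in zip(X.gene_ids, X.values):
            fh.write(gid + "\t" + "\t".join(_FMT.format(v) for v in row) + "\n")


def read_phenotype(path: str | Path) -> PhenotypeVector:
    """Read a two-column (sample_id, value) TSV with a header row."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    sample_ids: list[str] = []
    values: list[float] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
        if cells[0] in sample_ids:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {cells[0]!r}")
        sample_ids.append(cells[0])
        values.append(_parse_float(cells[1], str(path), lineno))
    return PhenotypeVector(values=values, sample_ids=sample_ids)


def write_phenotype(y: PhenotypeVector, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tphenotype\n")
        for sid, v in zip(y.sample_ids, y.values):
            fh.write(f"{sid}\t{_FMT.format(v)}\n")


def write_edge_list(E: EdgeSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tpcor\tscore\n")
        for a, b, r, s in E.edges:
            fh.write(f"{a}\t{b}\t{_FMT.format(r)}\t{_FMT.format(s)}\n")


def write_graphml(G: GeneNetwork, path: str | Path, E: EdgeSet | None = None) -> None:
    g = G.graph.copy()
    if E is not None:
        for a, b, r, s in E.edges:
            if g.has_edge(a, b):
                g[a][b]["pcor"] = float(r)
                g[a][b]["score"] = float(s)
    nx.write_graphml(g, str(path))


def write_node_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="gene_id", float_format="%.10g")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(_FMT.format(obj))
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), indent=1, sort_keys=True))
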