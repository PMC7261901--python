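"""Readers and writers for count matrices, tables, truth files and networks.

Everything is plain TSV/JSON/XML text. Readers validate eagerly and report
the offending line number; writers emit deterministic row and column
orderings so reruns are byte-identical.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import networkx as nx

from .simulate import ExpressionStudy, GroundTruth

__all__ = [
    "ParseError",
    "read_counts", "write_counts",
    "read_sample_sheet", "write_sample_sheet",
    "read_target_table", "write_target_table",
    "read_de_table", "write_de_table",
    "read_truth", "write_truth",
    "read_study",
    "write_network", "write_node_table",
]


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


def read_counts(path: str | Path) -> pd.DataFrame:
    """Integer count matrix from TSV (first column feature IDs, header row).

    Rejects duplicate feature IDs, ragged rows and non-integer entries,
    naming the offending line.
    """
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        samples = header[1:]
        ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[int]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} "
                                 f"columns, got {len(rec)}")
            fid = rec[0]
            if fid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            try:
                values = [int(v) for v in rec[1:]]
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count entry") from None
            if any(v < 0 for v in values):
                raise ParseError(f"{path}:{lineno}: negative count")
            ids.append(fid)
            rows.append(values)
    return pd.DataFrame(rows, index=ids, columns=samples, dtype="int64")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if sheet["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs")
    return sheet[["sample", "group"]]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[["sample", "group"]].to_csv(path, sep="\t", index=False)


def read_target_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t",
                        dtype={"mirna": str, "target": str,
                               "target_class": str, "mre_count": "int64"})
    required = ["mirna", "target", "target_class", "mre_count"]
    for col in required:
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if table.duplicated(subset=["mirna", "target"]).any():
        raise ParseError(f"{path}: duplicate (mirna, target) rows")
    if (table["mre_count"] < 1).any():
        raise ParseError(f"{path}: mre_count must be >= 1")
    bad = set(table["target_class"]) - {"mRNA", "lncRNA"}
    if bad:
        raise ParseError(f"{path}: unknown target_class values {sorted(bad)}")
    return table[required]


def write_target_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "de_features": sorted([f, d] for f, d in truth.de_features),
        "module_membership": dict(sorted(truth.module_membership.items())),
        "cerna_triples": [list(t) for t in truth.cerna_triples],
        "true_target_edges": sorted([m, t] for m, t in truth.true_target_edges),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        de_features={(f, d) for f, d in payload["de_features"]},
        module_membership=dict(payload["module_membership"]),
        cerna_triples=[tuple(t) for t in payload["cerna_triples"]],
        true_target_edges={(m, t) for m, t in payload["true_target_edges"]},
    )


def read_study(directory: str | Path) -> ExpressionStudy:
    """Load a fixture directory written by ``simulate.write_fixture``."""
    directory = Path(directory)
    counts = {cls: read_counts(directory / f"{cls}_counts.tsv")
              for cls in ("mrna", "lncrna", "mirna")}
    sheet = read_sample_sheet(directory / "samples.tsv")
    truth_path = directory / "truth.json"
    truth = read_truth(truth_path) if truth_path.exists() else None
    return ExpressionStudy(counts=counts, sample_sheet=sheet, truth=truth)


def _sorted_graph(graph: nx.Graph) -> nx.Graph:
    """Copy with nodes and edges in sorted order for deterministic output."""
    out = nx.Graph()
    for node in sorted(graph.nodes):
        out.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        out.add_edge(u, v, **graph.edges[u, v])
    return out


def write_network(graph: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Export a network as SIF, GraphML or a TSV edge table.

    SIF lines are "source<TAB>edgetype<TAB>target"; the edge type comes
    from the ``etype`` edge attribute (default "pp").
    """
    path = Path(path)
    g = _sorted_graph(graph)
    if fmt == "sif":
        lines = [f"{u}\t{d.get('etype', 'pp')}\t{v}"
                 for u, v, d in g.edges(data=True)]
        path.write_text("".join(line + "\n" for line in lines))
    elif fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "tsv":
        rows = [{"source": u, "target": v,
                 "etype": d.get("etype", "pp"),
                 "weight": d.get("weight", ""),
                 "p": d.get("p", "")} for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "etype",
                                    "weight", "p"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def write_node_table(graph: nx.Graph, path: str | Path) -> None:
    rows = [{"node": n,
             "node_class": d.get("node_class", ""),
             "direction": d.get("direction", ""),
             "degree": graph.degree(n)}
            for n, d in sorted(graph.nodes(data=True))]
    pd.DataFrame(rows, columns=["node", "node_class", "direction",
                                "degree"]).to_csv(path, sep="\t", index=False)
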