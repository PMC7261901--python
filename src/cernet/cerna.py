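"""lncRNA-miRNA-mRNA ceRNA network assembly.

Candidate lncRNA-mRNA pairs are screened by signed Pearson correlation
(PCC > pcc_min and p < alpha), then retained only if the two members share
more than ``min_shared - 1`` differentially expressed miRNAs in the target
table and the overlap is hypergeometrically significant. The result is a
tripartite graph with "coexp" (lncRNA-mRNA) and "targets" (miRNA-target)
edges, annotated with regulation directions and degree centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import networkx as nx

from .coexpression import _cross_correlation, correlation_pvalue

__all__ = [
    "pearson_test",
    "candidate_pairs",
    "shared_mirnas",
    "hypergeom_shared_test",
    "CeRNANetwork",
    "assemble_cerna",
    "degree_report",
    "extract_mirna_subnetwork",
]

PAIR_COLUMNS = ["lncrna", "mrna", "pcc", "pcc_p"]


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = float(correlation_pvalue(np.array([r]), n)[0])
    return r, p


def candidate_pairs(expr_lnc: pd.DataFrame, expr_mrna: pd.DataFrame,
                    de_lnc: Optional[pd.DataFrame] = None,
                    de_mrna: Optional[pd.DataFrame] = None,
                    pcc_min: float = 0.8, alpha: float = 0.05) -> pd.DataFrame:
    """Screen all DE lncRNA x DE mRNA pairs by signed correlation.

    The rule is strict and signed: pcc > pcc_min and p < alpha, so
    anti-correlated pairs never qualify (sponged partners co-vary
    positively). If DE tables are given, expression is first restricted to
    their up/down calls.
    """
    if de_lnc is not None:
        expr_lnc = expr_lnc.loc[expr_lnc.index.intersection(
            de_lnc.loc[de_lnc["call"] != "ns", "feature"])]
    if de_mrna is not None:
        expr_mrna = expr_mrna.loc[expr_mrna.index.intersection(
            de_mrna.loc[de_mrna["call"] != "ns", "feature"])]
    if expr_lnc.empty or expr_mrna.empty:
        warnings.warn("no DE features on one side; no candidate pairs")
        return pd.DataFrame(columns=PAIR_COLUMNS)
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("expression matrices must share sample columns")
    n = expr_lnc.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples")
    R = _cross_correlation(expr_lnc, expr_mrna)
    P = correlation_pvalue(R, n)
    keep = np.isfinite(R) & (R > pcc_min) & (P < alpha)
    rows, cols = np.where(keep)
    return pd.DataFrame({
        "lncrna": expr_lnc.index[rows],
        "mrna": expr_mrna.index[cols],
        "pcc": R[rows, cols],
        "pcc_p": P[rows, cols],
    })


def _targets_of(targets: pd.DataFrame, feature: str) -> pd.DataFrame:
    return targets[targets["target"] == feature]


def shared_mirnas(lncrna: str, mrna: str, targets: pd.DataFrame,
                  de_mirnas: set[str]) -> tuple[set[str], int, int]:
    """DE miRNAs targeting both members, plus each member's MRE sums.

    Returns (shared set, MRE count summed over shared miRNAs on the lncRNA,
    same on the mRNA).
    """
    lnc_rows = _targets_of(targets, lncrna)
    mrna_rows = _targets_of(targets, mrna)
    lnc_mirs = set(lnc_rows["mirna"]) & de_mirnas
    mrna_mirs = set(mrna_rows["mirna"]) & de_mirnas
    shared = lnc_mirs & mrna_mirs
    mre_lnc = int(lnc_rows.loc[lnc_rows["mirna"].isin(shared), "mre_count"].sum())
    mre_mrna = int(mrna_rows.loc[mrna_rows["mirna"].isin(shared), "mre_count"].sum())
    return shared, mre_lnc, mre_mrna


def _hypergeom_tail(N: int, K: int, n: int, x: int) -> Fraction:
    """Exact upper-tail hypergeometric probability as a rational number."""
    numerator = sum(comb(K, i) * comb(N - K, n - i)
                    for i in range(x, min(K, n) + 1))
    return Fraction(numerator, comb(N, n))


def hypergeom_shared_test(n_universe: int, n_target_lnc: int,
                          n_target_mrna: int, n_shared: int) -> float:
    """Upper-tail hypergeometric p of observing >= n_shared shared miRNAs.

    Drawing n_target_mrna miRNAs from a universe of n_universe of which
    n_target_lnc target the lncRNA: P(X >= n_shared). Computed with exact
    integer combinatorics, then converted to float.
    """
    N, K, n, x = n_universe, n_target_lnc, n_target_mrna, n_shared
    if not (0 <= x <= min(K, n) and max(K, n) <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, x={x}")
    return float(_hypergeom_tail(N, K, n, x))


@dataclass
class CeRNANetwork:
    """Tripartite ceRNA graph plus the retained pair table.

    Node attributes: node_class in {lncRNA, miRNA, mRNA}, direction in
    {up, down, ns}. Edge attribute ``etype`` is "coexp" or "targets".
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=PAIR_COLUMNS + ["shared_mirnas", "n_shared", "hypergeom_p"]))

    def validate(self) -> None:
        for u, v in self.graph.edges:
            cu = self.graph.nodes[u]["node_class"]
            cv = self.graph.nodes[v]["node_class"]
            if cu == cv:
                raise ValueError(f"edge within class {cu}: {u} - {v}")

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def _direction_map(de_tables: Mapping[str, pd.DataFrame]) -> dict[str, str]:
    out: dict[str, str] = {}
    for table in de_tables.values():
        out.update(zip(table["feature"], table["call"]))
    return out


def assemble_cerna(de_tables: Mapping[str, pd.DataFrame],
                   pairs: pd.DataFrame, targets: pd.DataFrame,
                   alpha: float = 0.05, min_shared: int = 2,
                   universe: Optional[int] = None) -> CeRNANetwork:
    """Assemble the tripartite network from screened pairs and targets.

    Keeps a candidate pair when it shares at least ``min_shared`` DE miRNAs
    (default 2, i.e. "more than 1") and the shared count is significant
    under the hypergeometric test at ``alpha`` (alpha >= 1 disables the
    test, e.g. for unfiltered exports). ``universe`` defaults to the number
    of DE miRNAs.
    """
    de_mirnas = set(de_tables["mirna"].loc[
        de_tables["mirna"]["call"] != "ns", "feature"])
    dir_map = _direction_map(de_tables)
    targets_de = targets[targets["mirna"].isin(de_mirnas)]
    N = len(de_mirnas) if universe is None else int(universe)

    net = CeRNANetwork()
    g = net.graph
    kept_rows = []
    mre_lookup = {(r.mirna, r.target): int(r.mre_count)
                  for r in targets_de.itertuples()}
    for row in pairs.itertuples():
        shared, mre_l, mre_m = shared_mirnas(row.lncrna, row.mrna,
                                             targets_de, de_mirnas)
        if len(shared) < min_shared:
            continue
        n_lnc = int((targets_de["target"] == row.lncrna).sum())
        n_mrna = int((targets_de["target"] == row.mrna).sum())
        p_hyp = hypergeom_shared_test(max(N, n_lnc, n_mrna), n_lnc,
                                      n_mrna, len(shared))
        if alpha < 1.0 and not p_hyp < alpha:
            continue
        kept_rows.append({
            "lncrna": row.lncrna, "mrna": row.mrna,
            "pcc": row.pcc, "pcc_p": row.pcc_p,
            "shared_mirnas": ";".join(sorted(shared)),
            "n_shared": len(shared), "hypergeom_p": p_hyp,
        })
        g.add_node(row.lncrna, node_class="lncRNA",
                   direction=dir_map.get(row.lncrna, "ns"))
        g.add_node(row.mrna, node_class="mRNA",
                   direction=dir_map.get(row.mrna, "ns"))
        g.add_edge(row.lncrna, row.mrna, etype="coexp",
                   weight=float(row.pcc), p=float(row.pcc_p),
                   hypergeom_p=p_hyp, n_shared=len(shared))
        for mir in sorted(shared):
            g.add_node(mir, node_class="miRNA",
                       direction=dir_map.get(mir, "ns"))
            for tgt in (row.lncrna, row.mrna):
                g.add_edge(mir, tgt, etype="targets",
                           mre_count=mre_lookup.get((mir, tgt), 1))
    net.pairs = pd.DataFrame(
        kept_rows, columns=PAIR_COLUMNS + ["shared_mirnas", "n_shared",
                                           "hypergeom_p"])
    net.validate()
    return net


def degree_report(network: CeRNANetwork) -> pd.DataFrame:
    """Nodes ranked by degree (descending), ties broken by node ID."""
    g = network.graph
    rows = [{
        "node": n,
        "node_class": d.get("node_class", "?"),
        "direction": d.get("direction", "ns"),
        "degree": g.degree(n),
    } for n, d in g.nodes(data=True)]
    table = pd.DataFrame(rows, columns=["node", "node_class",
                                        "direction", "degree"])
    if len(table):
        table = table.sort_values(["degree", "node"],
                                  ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def extract_mirna_subnetwork(network: CeRNANetwork,
                             mirna_id: str) -> CeRNANetwork:
    """The queried miRNA, its targets in the network, and the retained
    lncRNA-mRNA edges among those targets."""
    g = network.graph
    if mirna_id not in g:
        raise KeyError(f"miRNA {mirna_id!r} not present in the network")
    nodes = {mirna_id} | set(g.neighbors(mirna_id))
    sub = g.subgraph(nodes).copy()
    pairs = network.pairs
    keep = pairs["lncrna"].isin(nodes) & pairs["mrna"].isin(nodes)
    return CeRNANetwork(graph=sub, pairs=pairs[keep].reset_index(drop=True))
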