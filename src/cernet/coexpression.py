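"""Weighted lncRNA-mRNA co-expression networks.

Pipeline: similarity S = |Pearson r|, soft-threshold adjacency a = S**beta
(integer beta chosen by the scale-free topology criterion), weighted
connectivity k = row sums, topological overlap (unsigned TOM), average-
linkage clustering of 1 - TOM into modules, and a thresholded
lncRNA-mRNA edge network with hub extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "similarity",
    "soft_adjacency",
    "connectivity",
    "ScaleFreeFit",
    "scale_free_fit",
    "BetaSweep",
    "pick_beta",
    "tom",
    "tom_dissimilarity",
    "cluster_modules",
    "correlation_pvalue",
    "build_lnc_mrna_network",
    "extract_hub_subnetwork",
]


def similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation between feature expression profiles.

    ``expr`` is features x samples. Zero-variance features are dropped with
    a warning (their correlation is undefined). Diagonal is exactly 1.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(expr.index[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}")
        arr = arr[keep]
    index = expr.index[keep]
    if arr.shape[0] == 0:
        raise ValueError("all features have zero variance")
    S = np.abs(np.corrcoef(arr))
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=index, columns=index)


def _check_beta(beta) -> int:
    if isinstance(beta, float) and not beta.is_integer():
        raise ValueError("beta must be a positive integer")
    beta = int(beta)
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    return beta


def soft_adjacency(S: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Elementwise power a_ij = S_ij**beta with the diagonal zeroed."""
    beta = _check_beta(beta)
    A = S.to_numpy(dtype=float) ** beta
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=S.index, columns=S.columns)


def connectivity(A: pd.DataFrame) -> pd.Series:
    """Weighted degree k_i = sum_j a_ij (diagonal excluded by construction)."""
    arr = A.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    return pd.Series(arr.sum(axis=1), index=A.index, name="k")


@dataclass(frozen=True)
class ScaleFreeFit:
    """Log-log regression of binned connectivity frequency on connectivity."""

    signed_r2: float  # -sign(slope) * R^2
    slope: float      # estimate of -gamma
    mean_k: float
    n_bins: int
    beta: Optional[int] = None


def scale_free_fit(k: Sequence[float], n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10 p(k) ~ log10 k over equal-width connectivity bins.

    p(k) is the per-bin frequency and k the per-bin mean connectivity;
    empty bins and bins with non-positive mean k are dropped.
    """
    k = np.asarray(k, dtype=float)
    if k.size == 0 or k.max() <= 0:
        raise ValueError("connectivity vector has no positive entries")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    bin_mean_k = np.divide(sums, counts, out=np.zeros_like(sums),
                           where=nonempty)
    usable = nonempty & (bin_mean_k > 0)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable connectivity bins; fit unidentifiable")
    x = np.log10(bin_mean_k[usable])
    y = np.log10(counts[usable] / k.size)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ScaleFreeFit(signed_r2=float(-np.sign(slope) * r2),
                        slope=float(slope), mean_k=float(k.mean()),
                        n_bins=int(usable.sum()))


@dataclass
class BetaSweep:
    """Result of the soft-threshold sweep: per-beta fits and the choice."""

    chosen_beta: int
    fits: pd.DataFrame  # columns: beta, signed_r2, slope, mean_k, n_bins
    scale_free: bool    # whether the chosen beta met the criterion


def pick_beta(expr: pd.DataFrame, betas: Sequence[int] = range(1, 31),
              r2_target: float = 0.8, min_mean_k: float = 1.0,
              n_bins: int = 10) -> BetaSweep:
    """Scale-free topology criterion over a beta sweep.

    Chooses the smallest beta whose fit reaches ``signed_r2 >= r2_target``
    while mean connectivity stays >= ``min_mean_k``; if none qualifies,
    falls back to the beta maximizing signed R^2 (flagged scale_free=False).
    """
    betas = list(betas)
    if not betas:
        raise ValueError("empty beta range")
    S = similarity(expr)
    rows = []
    for beta in betas:
        A = soft_adjacency(S, beta)
        k = connectivity(A).to_numpy()
        try:
            fit = scale_free_fit(k, n_bins=n_bins)
        except ValueError as exc:
            warnings.warn(f"beta={beta}: scale-free fit failed ({exc}); skipped")
            rows.append((beta, np.nan, np.nan, float(np.mean(k)), 0))
            continue
        rows.append((beta, fit.signed_r2, fit.slope, fit.mean_k, fit.n_bins))
    fits = pd.DataFrame(rows, columns=["beta", "signed_r2", "slope",
                                       "mean_k", "n_bins"])
    ok = fits[(fits["signed_r2"] >= r2_target) & (fits["mean_k"] >= min_mean_k)]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
        return BetaSweep(chosen_beta=chosen, fits=fits, scale_free=True)
    if fits["signed_r2"].notna().sum() == 0:
        raise ValueError("scale-free fit failed for every beta")
    chosen = int(fits.loc[fits["signed_r2"].idxmax(), "beta"])
    warnings.warn(f"no beta met signed R^2 >= {r2_target} with mean k >= "
                  f"{min_mean_k}; falling back to beta={chosen}")
    return BetaSweep(chosen_beta=chosen, fits=fits, scale_free=False)


def _check_adjacency(A: np.ndarray) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(A), 0.0):
        raise ValueError("adjacency diagonal must be zero")


def tom(A: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj over u != i, j; the diagonal is 1 by convention.
    """
    arr = A.to_numpy(dtype=float)
    _check_adjacency(arr)
    k = arr.sum(axis=1)
    L = arr @ arr  # diagonal of A is zero, so u = i, j contribute nothing
    denom = np.minimum.outer(k, k) + 1.0 - arr
    assert (denom > 0).all(), "TOM denominator must be positive"
    T = (L + arr) / denom
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=A.index, columns=A.columns)


def tom_dissimilarity(A: pd.DataFrame) -> pd.DataFrame:
    """1 - TOM, the clustering distance."""
    return 1.0 - tom(A)


def cluster_modules(dissimilarity: pd.DataFrame, cut_height: float = 0.95,
                    min_module_size: int = 3,
                    linkage_method: str = "average") -> pd.Series:
    """Hierarchical module detection on a TOM dissimilarity.

    Average-linkage agglomeration with a static cut at ``cut_height``;
    clusters smaller than ``min_module_size`` are labelled 0 (unassigned),
    the rest are renumbered 1, 2, ... by decreasing size (ties broken by
    first member) so labels are deterministic.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError("cut_height must be in (0, 1]")
    D = dissimilarity.to_numpy(dtype=float).copy()
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method=linkage_method)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros_like(raw)
    sizes = pd.Series(raw).value_counts()
    kept = [(int(c), int(n)) for c, n in sizes.items() if n >= min_module_size]
    first_member = {c: int(np.argmax(raw == c)) for c, _ in kept}
    kept.sort(key=lambda cn: (-cn[1], first_member[cn[0]]))
    for new, (old, _) in enumerate(kept, start=1):
        labels[raw == old] = new
    return pd.Series(labels, index=dissimilarity.index, name="module")


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def _cross_correlation(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> np.ndarray:
    """Pearson correlation of every row of a against every row of b."""
    a = expr_a.to_numpy(dtype=float)
    b = expr_b.to_numpy(dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a ** 2).sum(axis=1))
    sb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (a @ b.T) / np.outer(sa, sb)
    return R


def build_lnc_mrna_network(expr_lnc: pd.DataFrame, expr_mrna: pd.DataFrame,
                           pcc_min: float = 0.8,
                           alpha: float = 0.05) -> nx.Graph:
    """Bipartite lncRNA-mRNA network of strongly correlated pairs.

    Edge rule: |PCC| > pcc_min (strict) and correlation-test p < alpha.
    Node attribute ``node_class`` is "lncRNA" or "mRNA"; edges carry the
    signed correlation (``weight``) and its p-value.
    """
    if list(expr_lnc.columns) != list(expr_mrna.columns):
        raise ValueError("lncRNA and mRNA matrices must share sample columns")
    n = expr_lnc.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for the correlation test (df >= 2)")
    R = _cross_correlation(expr_lnc, expr_mrna)
    P = correlation_pvalue(R, n)
    g = nx.Graph()
    for node in expr_lnc.index:
        g.add_node(node, node_class="lncRNA")
    for node in expr_mrna.index:
        g.add_node(node, node_class="mRNA")
    rows, cols = np.where((np.abs(R) > pcc_min) & (P < alpha) & np.isfinite(R))
    for i, j in zip(rows, cols):
        g.add_edge(expr_lnc.index[i], expr_mrna.index[j], etype="pp",
                   weight=float(R[i, j]), p=float(P[i, j]))
    return g


def extract_hub_subnetwork(network: nx.Graph, min_degree: int) -> nx.Graph:
    """Hub lncRNAs (degree >= min_degree) with their neighbors and edges."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    if min_degree == 0:
        return network.copy()
    hubs = [n for n, d in network.nodes(data=True)
            if d.get("node_class") == "lncRNA"
            and network.degree(n) >= min_degree]
    nodes = set(hubs)
    sub = nx.Graph()
    for hub in hubs:
        sub.add_node(hub, **network.nodes[hub])
        for nb in network.neighbors(hub):
            nodes.add(nb)
            sub.add_node(nb, **network.nodes[nb])
            sub.add_edge(hub, nb, **network.edges[hub, nb])
    return sub
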