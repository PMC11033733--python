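"""Spearman co-occurrence networks, topology, KS comparisons and the
Integrated Value of Influence (IVI) node-influence composite."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FeatureTable, relative_abundance

__all__ = [
    "TopologySummary",
    "build_network",
    "topology",
    "compare_degree_distributions",
    "ivi",
    "top_influential",
    "write_edge_list",
]


@dataclass
class TopologySummary:
    modularity: float
    average_degree: float
    clustering_coefficient: float
    n_nodes: int
    n_edges: int


def build_network(
    table: FeatureTable,
    r_min: float = 0.6,
    p_max: float = 0.05,
    use: str = "relative",
) -> nx.Graph:
    """Positive Spearman co-occurrence network over taxa.

    Edges require r > r_min AND p < p_max (both strict).  Correlations are
    computed on relative abundances by default (``use="counts"`` switches to
    raw counts).  Constant taxa are excluded; isolated nodes are dropped.
    """
    if table.n_samples < 4:
        raise ValueError("network construction requires at least 4 samples")
    data = relative_abundance(table) if use == "relative" else table.counts.astype(float)
    variable = np.array([np.unique(col).size > 1 for col in data.T])
    if not variable.all():
        dropped = [t for t, v in zip(table.taxon_ids, variable) if not v]
        warnings.warn(f"excluding constant taxa from correlation: {dropped}")
    data = data[:, variable]
    taxa = [t for t, v in zip(table.taxon_ids, variable) if v]
    if len(taxa) < 2:
        return nx.Graph()
    if len(taxa) == 2:
        res = stats.spearmanr(data[:, 0], data[:, 1])
        r = np.array([[1.0, res.statistic], [res.statistic, 1.0]])
        p = np.array([[0.0, res.pvalue], [res.pvalue, 0.0]])
    else:
        res = stats.spearmanr(data)
        r = np.asarray(res.statistic)
        p = np.asarray(res.pvalue)
    g = nx.Graph()
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            if r[i, j] > r_min and p[i, j] < p_max:
                g.add_edge(taxa[i], taxa[j], spearman_r=float(r[i, j]), p=float(p[i, j]))
    return g


def topology(net: nx.Graph, seed: int = 0) -> TopologySummary:
    """Modularity (best-of-10 Louvain), average degree 2E/N and mean local
    clustering (degree < 2 nodes contribute 0)."""
    n = net.number_of_nodes()
    if n == 0:
        return TopologySummary(float("nan"), float("nan"), float("nan"), 0, 0)
    e = net.number_of_edges()
    best_q = -math.inf
    for r in range(10):
        parts = nx.community.louvain_communities(net, seed=seed + r)
        q = nx.community.modularity(net, parts)
        best_q = max(best_q, q)
    avg_deg = 2.0 * e / n
    clustering = float(np.mean(list(nx.clustering(net).values())))
    return TopologySummary(float(best_q), avg_deg, clustering, n, e)


def compare_degree_distributions(
    net_a: nx.Graph, net_b: nx.Graph, property: str = "degree"
) -> tuple[float, float]:
    """Two-sample KS test on per-node degree (or local clustering)
    distributions; asymptotic p."""
    for net in (net_a, net_b):
        if net.number_of_nodes() < 2:
            raise ValueError("KS comparison requires networks with >= 2 nodes")
    if property == "degree":
        a = [d for _, d in net_a.degree()]
        b = [d for _, d in net_b.degree()]
    elif property == "clustering":
        a = list(nx.clustering(net_a).values())
        b = list(nx.clustering(net_b).values())
    else:
        raise ValueError(f"unknown property: {property!r}")
    res = stats.ks_2samp(a, b, mode="asymp")
    return float(res.statistic), float(res.pvalue)


def _local_h_index(net: nx.Graph, node) -> int:
    degs = sorted((net.degree(v) for v in net.neighbors(node)), reverse=True)
    h = 0
    for i, d in enumerate(degs, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


def _collective_influence(net: nx.Graph, node, radius: int) -> float:
    k = net.degree(node)
    lengths = nx.single_source_shortest_path_length(net, node, cutoff=radius)
    frontier = [v for v, d in lengths.items() if d == radius]
    return (k - 1) * sum(net.degree(v) - 1 for v in frontier)


def _minmax_scale(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.full_like(values, lo, dtype=float)
    return lo + (values - vmin) * (hi - lo) / (vmax - vmin)


def ivi(net: nx.Graph, ci_radius: int = 2) -> pd.Series:
    """Integrated Value of Influence in [0, 1]; 1 marks the most influential
    node(s).

    Components: degree, local H-index, neighborhood connectivity (mean
    neighbor degree), ClusterRank (10^(-c) damping), betweenness, collective
    influence at ``ci_radius``.  Components are min-max scaled to [1, 100];
    IVI_raw = (degree + H-index) * (NC + ClusterRank) * (betweenness + CI),
    then min-max scaled to [0, 1] (an all-equal graph scores 1 everywhere).
    """
    nodes = list(net.nodes())
    if not nodes:
        return pd.Series(dtype=float, name="ivi")
    if any(net.degree(v) == 0 for v in nodes):
        raise ValueError("ivi requires every node to sit in a component of size >= 2")
    deg = np.array([net.degree(v) for v in nodes], dtype=float)
    h_index = np.array([_local_h_index(net, v) for v in nodes], dtype=float)
    nc = np.array(
        [np.mean([net.degree(u) for u in net.neighbors(v)]) for v in nodes]
    )
    clust = nx.clustering(net)
    cr = np.array(
        [
            10.0 ** (-clust[v]) * sum(net.degree(u) + 1 for u in net.neighbors(v))
            for v in nodes
        ]
    )
    btw = nx.betweenness_centrality(net, normalized=True)
    btw = np.array([btw[v] for v in nodes])
    ci = np.array([_collective_influence(net, v, ci_radius) for v in nodes])

    sdeg, shi, snc, scr, sbtw, sci = (
        _minmax_scale(x, 1.0, 100.0) for x in (deg, h_index, nc, cr, btw, ci)
    )
    hubness = sdeg + shi
    spreading = (snc + scr) * (sbtw + sci)
    raw = hubness * spreading
    if raw.max() == raw.min():
        scores = np.ones_like(raw)
    else:
        scores = (raw - raw.min()) / (raw.max() - raw.min())
    return pd.Series(scores, index=nodes, name="ivi")


def top_influential(scores: pd.Series, net: nx.Graph, fraction: float = 0.10) -> list[str]:
    """Top ceil(fraction * N) nodes; ties broken by score, degree, then ID."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(scores)
    k = math.ceil(fraction * n)
    order = sorted(
        scores.index, key=lambda v: (-scores[v], -net.degree(v), str(v))
    )
    return order[:k]


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "spearman_r": d.get("spearman_r"), "p": d.get("p")}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "spearman_r", "p"]).to_csv(
        path, sep="\t", index=False
    )
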