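"""Genus co-occurrence network.

All-pairs Spearman correlations thresholded on |rho| and p form the network;
degree and betweenness rank the genera, hubs are taken from the joint top of
both rankings, and observed graph properties are compared against
Erdos-Renyi ensembles with matched node/edge counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable

__all__ = [
    "build_network",
    "node_centralities",
    "identify_hubs",
    "random_network_comparison",
    "NetworkGraph",
    "spearman_pvalue",
]


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via the t approximation."""
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * st.t.sf(t, df=n - 2))


@dataclass
class NetworkGraph:
    """Thresholded co-occurrence network plus per-node and graph statistics."""

    graph: nx.Graph
    edges: pd.DataFrame  # source, target, rho, p, sign
    nodes: pd.DataFrame  # taxon, mean_abundance, degree, betweenness
    properties: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    table: AbundanceTable,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    positive_only: bool = False,
    fdr: bool = False,
) -> NetworkGraph:
    """Build the Spearman co-occurrence network over all genus pairs.

    An edge is kept iff |rho| > rho_min (rho > rho_min with
    ``positive_only``) and p < alpha; ``fdr=True`` gates on BH-adjusted p
    instead of raw p. Constant genera are excluded with a warning.
    """
    X = table.data
    if X.shape[0] < 5:
        raise ValueError("need >= 5 samples for a co-occurrence network")
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        warnings.warn(f"excluding constant taxa from network: {constant}", UserWarning, stacklevel=2)
        X = X.drop(columns=constant)
    taxa = list(X.columns)
    n = X.shape[0]
    rho_mat = st.spearmanr(X.to_numpy()).statistic
    rho_mat = np.atleast_2d(rho_mat)

    pairs = []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        rho = float(rho_mat[i, j])
        pairs.append((taxa[i], taxa[j], rho, spearman_pvalue(rho, n)))
    edges = pd.DataFrame(pairs, columns=["source", "target", "rho", "p"])
    gate_p = multipletests(edges["p"], method="fdr_bh")[1] if fdr else edges["p"].to_numpy()
    strength = edges["rho"] if positive_only else edges["rho"].abs()
    keep = (strength > rho_min) & (gate_p < alpha)
    edges = edges.loc[keep].reset_index(drop=True)
    edges["sign"] = np.sign(edges["rho"]).astype(int)

    G = nx.Graph()
    G.add_nodes_from(taxa)
    for _, row in edges.iterrows():
        G.add_edge(row["source"], row["target"], rho=row["rho"], p=row["p"], sign=int(row["sign"]))

    mean_ab = X.mean(axis=0)
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=True)
    nodes = pd.DataFrame(
        {
            "taxon": taxa,
            "mean_abundance": [mean_ab[t] for t in taxa],
            "degree": [deg[t] for t in taxa],
            "betweenness": [btw[t] for t in taxa],
        }
    )
    props = _graph_properties(G)
    return NetworkGraph(
        graph=G,
        edges=edges,
        nodes=nodes,
        properties=props,
        params={"rho_min": rho_min, "alpha": alpha, "positive_only": positive_only, "fdr": fdr},
    )


def _graph_properties(G: nx.Graph) -> dict:
    n = G.number_of_nodes()
    props = {
        "n_nodes": n,
        "n_edges": G.number_of_edges(),
        "density": nx.density(G) if n > 1 else 0.0,
        "clustering": nx.average_clustering(G) if n else 0.0,
    }
    if G.number_of_edges():
        comp = max(nx.connected_components(G), key=len)
        sub = G.subgraph(comp)
        props["mean_path_length"] = nx.average_shortest_path_length(sub) if len(sub) > 1 else 0.0
        comms = nx.algorithms.community.greedy_modularity_communities(G)
        props["modularity"] = nx.algorithms.community.modularity(G, comms)
    else:
        props["mean_path_length"] = np.nan
        props["modularity"] = np.nan
    return props


def node_centralities(net: NetworkGraph) -> pd.DataFrame:
    """Degree and normalized betweenness per node (Brandes algorithm)."""
    return net.nodes[["taxon", "degree", "betweenness"]].copy()


def identify_hubs(net: NetworkGraph, top_frac: float = 0.05, betweenness_frac: float = 0.20) -> pd.DataFrame:
    """Rank nodes by degree (betweenness as tiebreak) and flag hubs.

    Hubs are nodes in the top ``top_frac`` of the degree ranking AND the top
    ``betweenness_frac`` of the betweenness ranking; ties on a completely
    flat degree sequence yield no hubs, but the full ranking is always
    returned.
    """
    nodes = net.nodes.sort_values(
        ["degree", "betweenness", "taxon"], ascending=[False, False, True]
    ).reset_index(drop=True)
    nodes["rank"] = np.arange(1, len(nodes) + 1)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    deg_cut = max(1, int(np.ceil(top_frac * n)))
    btw_cut = max(1, int(np.ceil(betweenness_frac * n)))
    deg_sorted = nodes["degree"].to_numpy()
    btw_order = nodes.sort_values(["betweenness", "degree"], ascending=False)["taxon"].to_list()
    top_deg = set(nodes["taxon"].iloc[:deg_cut])
    top_btw = set(btw_order[:btw_cut])
    if deg_sorted.max() == deg_sorted.min():
        hubs = set()  # flat degree sequence: no meaningful hub
    else:
        # extend the degree cut through ties at the boundary value
        boundary = deg_sorted[deg_cut - 1]
        top_deg = set(nodes.loc[nodes["degree"] >= boundary, "taxon"])
        hubs = top_deg & top_btw
    nodes["is_hub"] = nodes["taxon"].isin(hubs)
    return nodes


def random_network_comparison(net: NetworkGraph, n_rand: int = 100, seed: int = 0) -> pd.DataFrame:
    """Compare graph properties against Erdos-Renyi graphs of identical size.

    Generates ``n_rand`` G(n, m) graphs and reports observed value, random
    mean/sd and z-score for clustering coefficient, mean path length and
    modularity.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    G = net.graph
    if G.number_of_edges() == 0:
        raise ValueError("cannot compare an edgeless graph to random graphs")
    n, m = G.number_of_nodes(), G.number_of_edges()
    rng = np.random.default_rng(seed)
    rand_props = {"clustering": [], "mean_path_length": [], "modularity": []}
    for _ in range(n_rand):
        R = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        p = _graph_properties(R)
        for k in rand_props:
            rand_props[k].append(p[k])
    rows = []
    for k, vals in rand_props.items():
        vals = np.asarray(vals, dtype=float)
        obs = float(net.properties[k])
        mu, sd = float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))
        z = (obs - mu) / sd if sd > 0 else np.nan
        rows.append((k, obs, mu, sd, z))
    return pd.DataFrame(rows, columns=["property", "observed", "random_mean", "random_sd", "z"])
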