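"""Thresholded Spearman co-occurrence networks and topology metrics.

A global network is built over the most abundant taxa from all samples:
nodes are taxa, and an undirected signed edge connects two taxa when the
Spearman rank correlation of their abundances across samples is strong
(|r| > 0.75) and significant (p < 0.001, t-approximation). Group-specific
subnetworks are extracted from the global network by restricting to taxa
observed in the group's samples and pruning newly isolated nodes; their
topology (density, mean degree, transitivity, Freeman degree
centralization, proportion of negative edges) summarises how group
membership reshapes putative interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .core_io import CommunityTable, SampleMetadata, top_abundant_taxa

logger = logging.getLogger("ecoassembly")

__all__ = [
    "CooccurrenceNetwork",
    "TopologyMetrics",
    "spearman_edges",
    "build_global_network",
    "extract_subnetwork",
    "topology_metrics",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected signed co-occurrence graph over taxa."""

    graph: nx.Graph  # edges carry r, p, sign attributes
    provenance: str = "global"
    r_min: float = 0.75
    p_max: float = 0.001

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, d["r"], d["p"], d["sign"]) for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "sign"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass
class TopologyMetrics:
    """Whole-network topology summary; transitivity and centralization are
    None when fewer than 3 nodes make them undefined."""

    n_nodes: int
    n_edges: int
    edge_density: float
    mean_degree: float
    transitivity: float | None
    degree_centralization: float | None
    proportion_negative: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "edge_density": self.edge_density,
            "mean_degree": self.mean_degree,
            "transitivity": self.transitivity,
            "degree_centralization": self.degree_centralization,
            "proportion_negative": self.proportion_negative,
        }


def spearman_edges(
    table: CommunityTable,
    r_min: float = 0.75,
    p_max: float = 0.001,
    fdr: bool = False,
) -> pd.DataFrame:
    """All taxon pairs passing |r| > r_min and p < p_max (both strict).

    Spearman r is Pearson correlation of mid-ranked abundances across
    samples; the two-sided p-value uses the t-approximation
    t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom. Taxa with constant
    abundance have no defined rank correlation and are skipped with a
    warning. With ``fdr=True`` p-values are Benjamini-Hochberg adjusted
    before thresholding.
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("Spearman edge detection requires at least 4 samples")
    counts = table.values.astype(float)
    taxa = table.taxon_ids
    constant = np.ptp(counts, axis=1) == 0
    if constant.any():
        logger.warning(
            "spearman_edges: skipping %d constant taxa", int(constant.sum())
        )
    ranks = np.apply_along_axis(rankdata, 1, counts)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.square(centered).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (centered @ centered.T) / np.outer(norms, norms)
    corr = np.clip(corr, -1.0, 1.0)

    iu = np.triu_indices(len(taxa), k=1)
    r = corr[iu]
    valid = ~(constant[iu[0]] | constant[iu[1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * t_dist.sf(np.abs(tval), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_adj = np.full_like(p, np.nan)
        p_adj[valid] = multipletests(p[valid], method="fdr_bh")[1]
        p = p_adj

    keep = valid & (np.abs(r) > r_min) & (p < p_max)
    rows = [
        (taxa[i], taxa[j], float(r[k]), float(p[k]), int(np.sign(r[k])))
        for k, (i, j) in enumerate(zip(iu[0], iu[1]))
        if keep[k]
    ]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "sign"])


def build_global_network(
    table: CommunityTable,
    k: int = 400,
    r_min: float = 0.75,
    p_max: float = 0.001,
    fdr: bool = False,
) -> CooccurrenceNetwork:
    """Global co-occurrence network over the top-k most abundant taxa.

    Isolated nodes (taxa passing the abundance cut but with no significant
    correlation) are retained at this stage; subnetwork extraction prunes
    them later.
    """
    top = top_abundant_taxa(table, k=k)
    edges = spearman_edges(top, r_min=r_min, p_max=p_max, fdr=fdr)
    g = nx.Graph()
    g.add_nodes_from(top.taxon_ids)
    for row in edges.itertuples():
        g.add_edge(row.taxon_a, row.taxon_b, r=row.r, p=row.p, sign=row.sign)
    return CooccurrenceNetwork(g, provenance="global", r_min=r_min, p_max=p_max)


def extract_subnetwork(
    global_net: CooccurrenceNetwork,
    table: CommunityTable,
    meta: SampleMetadata,
    group: str,
) -> CooccurrenceNetwork:
    """Group subnetwork: keep global nodes with nonzero abundance in the
    group's samples and the global edges between them, then drop nodes left
    isolated by the restriction."""
    samples = [s for s in meta.samples_in(group) if s in table.sample_ids]
    if not samples:
        raise KeyError(f"group {group!r} has no samples in the table")
    sub_table = table.select_samples(samples)
    totals = sub_table.data.sum(axis=1)
    present = {t for t in global_net.graph.nodes if totals.get(t, 0) > 0}
    sub = global_net.graph.subgraph(present).copy()
    sub.remove_nodes_from([n for n, deg in dict(sub.degree()).items() if deg == 0])
    return CooccurrenceNetwork(
        sub,
        provenance=f"subnetwork of group {group}",
        r_min=global_net.r_min,
        p_max=global_net.p_max,
    )


def topology_metrics(net: CooccurrenceNetwork) -> TopologyMetrics:
    """Topology summary of a network.

    Density = 2E/(n(n-1)); transitivity = 3 triangles / connected triples;
    degree centralization = sum_i (d_max - d_i) / ((n-1)(n-2)) (Freeman).
    """
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        logger.warning("topology_metrics: empty network")
        return TopologyMetrics(0, 0, 0.0, 0.0, None, None, 0.0)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_degree = 2.0 * e / n
    if n >= 3:
        transitivity = nx.transitivity(g)
        degrees = np.array([d for _, d in g.degree()])
        centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        transitivity = None
        centralization = None
    negative = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", 1) < 0)
    prop_neg = negative / e if e else 0.0
    return TopologyMetrics(
        n, e, density, mean_degree, transitivity, centralization, prop_neg
    )
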