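"""Module subnetwork extraction, centralities, and hub calling.

A module's co-expression subnetwork keeps edges whose adjacency exceeds a
weight cutoff. Five centralities are computed per node — weighted degree
(strength), betweenness and harmonic closeness on 1/weight distances,
eigenvector centrality on the weight matrix, and PageRank — ranked, and
aggregated with the Robust Rank Aggregation order-statistic score: for a
gene with sorted normalized ranks r_(1) ≤ … ≤ r_(K), the rho score is the
smallest binomial tail P(Bin(K, r_(k)) ≥ k); it is Bonferroni-corrected
within-gene (×K) and across genes (×n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import AdjacencyMatrix, ModulePartition

__all__ = ["HubReport", "extract_subnetwork", "centralities", "rra_aggregate"]

CENTRALITY_NAMES = ("degree", "betweenness", "closeness", "eigenvector", "pagerank")


@dataclass
class HubReport:
    """Per-gene centralities, ranks, rho score, adjusted p, and hub flag."""

    table: pd.DataFrame  # index gene; centralities, ranks, rho, score, padj, hub
    alpha: float = 0.05

    @property
    def hub_genes(self) -> list[str]:
        return list(self.table.index[self.table["hub"]])


def extract_subnetwork(
    adj: AdjacencyMatrix,
    labels: ModulePartition,
    module: str,
    weight_cutoff: float = 0.4,
) -> nx.Graph:
    """Weighted subgraph of a module's genes; edges where adjacency exceeds
    the cutoff; isolated nodes retained."""
    genes = labels.genes_in(module)
    if not genes:
        raise ValueError(f"module {module!r} is empty or unknown")
    sub = adj.values.loc[genes, genes].to_numpy()
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = sub[iu, ju] > weight_cutoff
    for i, j in zip(iu[mask], ju[mask]):
        g.add_edge(genes[i], genes[j], weight=float(sub[i, j]))
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Five weighted centralities per node.

    Path-based measures use distance = 1/weight; closeness is the harmonic
    variant (robust to disconnected components); eigenvector centrality is
    the non-negative principal eigenvector of the weight matrix; PageRank
    uses damping 0.85 on edge weights.
    """
    nodes = list(g.nodes)
    if len(nodes) < 2:
        warnings.warn("single-node graph; all centralities zero", stacklevel=2)
        return pd.DataFrame(0.0, index=nodes, columns=list(CENTRALITY_NAMES))
    for u, v, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"]
    degree = dict(g.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=True)
    closeness = nx.harmonic_centrality(g, distance="distance")
    n = len(nodes)
    closeness = {v: c / (n - 1) for v, c in closeness.items()}
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    if A.any():
        vals, vecs = np.linalg.eigh(A)
        lead = vecs[:, np.argmax(vals)]
        if lead.sum() < 0:
            lead = -lead
        lead = np.abs(lead)  # Perron vector of a nonnegative symmetric matrix
        eigen = {v: float(x) for v, x in zip(nodes, lead)}
    else:
        eigen = {v: 0.0 for v in nodes}
    pagerank = nx.pagerank(g, alpha=0.85, weight="weight")
    return pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "betweenness": pd.Series(betweenness, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
            "eigenvector": pd.Series(eigen, dtype=float),
            "pagerank": pd.Series(pagerank, dtype=float),
        }
    ).loc[nodes]


def _normalized_ranks(values: pd.Series) -> pd.Series:
    """Descending ranks (1 = most central), average ties, scaled by n."""
    ranks = stats.rankdata(-values.to_numpy(), method="average")
    return pd.Series(ranks / len(values), index=values.index)


def rra_aggregate(
    rank_lists: pd.DataFrame | list[pd.Series],
    alpha: float = 0.05,
) -> HubReport:
    """Robust Rank Aggregation of K rank lists over the same genes.

    ``rank_lists`` may be a genes × K table of centrality values (ranked
    internally, descending, average ties) or a list of normalized-rank
    series. Per gene: rho = min_k P(Bin(K, r_(k)) ≥ k) over the sorted
    normalized ranks; score = min(K·rho, 1); hub when n·score < alpha.
    """
    if isinstance(rank_lists, pd.DataFrame):
        series = [rank_lists[c] for c in rank_lists.columns]
    else:
        series = list(rank_lists)
    index = series[0].index
    for s in series[1:]:
        if set(s.index) != set(index):
            raise ValueError("rank lists cover different gene sets")
    R = np.column_stack([
        _normalized_ranks(s).reindex(index).to_numpy() for s in series
    ])
    n, K = R.shape
    R.sort(axis=1)
    ks = np.arange(1, K + 1)
    # P(Beta(k, K−k+1) <= r) == P(Bin(K, r) >= k)
    pk = stats.binom.sf(ks[None, :] - 1, K, R)
    rho = pk.min(axis=1)
    score = np.minimum(K * rho, 1.0)
    padj = np.minimum(n * score, 1.0)
    table = pd.DataFrame(
        {"rho": rho, "score": score, "padj": padj, "hub": n * score < alpha},
        index=index,
    )
    return HubReport(table, alpha=alpha)


def hub_report(
    adj: AdjacencyMatrix,
    labels: ModulePartition,
    module: str,
    weight_cutoff: float = 0.4,
    alpha: float = 0.05,
) -> tuple[HubReport, nx.Graph]:
    """End-to-end hub calling for one module: subnetwork → centralities →
    ranks → RRA; the report carries the centrality values and ranks."""
    g = extract_subnetwork(adj, labels, module, weight_cutoff)
    cent = centralities(g)
    report = rra_aggregate(cent, alpha=alpha)
    ranks = cent.apply(lambda col: stats.rankdata(-col.to_numpy(), method="average"))
    ranks.columns = [f"rank_{c}" for c in cent.columns]
    report.table = pd.concat([cent, ranks, report.table], axis=1)
    return report, g
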