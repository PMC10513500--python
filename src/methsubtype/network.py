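"""Gene correlation networks, MST reduction, and community detection.

Builds a Pearson-correlation graph over genes (edges kept only when
r > 0.6, strictly), prunes weakly connected genes (< 2 adjacent edges,
single pass), reduces to a minimum spanning tree under the weight 1 - r
(Prim's algorithm, so the strongest correlations are retained), and
partitions genes into communities by Girvan-Newman edge-betweenness
removal at maximum modularity.  Vertex display sizes are mean beta x 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkParams",
    "GeneNetwork",
    "correlation_matrix",
    "build_graph",
    "minimum_spanning_tree",
    "communities",
    "augment_clusters",
]


@dataclass(frozen=True)
class NetworkParams:
    """Edge/vertex filters and display scaling for the gene graph."""

    r_threshold: float = 0.6
    min_degree: int = 2
    size_scale: float = 10.0

    def __post_init__(self) -> None:
        if not -1.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (-1, 1)")
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")


@dataclass
class GeneNetwork:
    """Correlation-weighted gene graph with optional community labels."""

    graph: nx.Graph
    params: NetworkParams = field(default_factory=NetworkParams)
    community: dict[str, int] | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": data["r"]}
            for a, b, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations from a gene x sample matrix.

    Constant genes (zero variance, correlation undefined) are excluded
    with a warning.
    """
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation estimates")
    v = values.to_numpy(dtype=float)
    sd = v.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) with undefined correlation"
        )
        values = values.loc[~constant]
        v = values.to_numpy(dtype=float)
    r = np.corrcoef(v)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


def build_graph(
    r: pd.DataFrame, beta_means: pd.Series, params: NetworkParams | None = None
) -> GeneNetwork:
    """Threshold the correlation matrix into a filtered gene graph.

    Edges are kept iff r > r_threshold (strict; an edge at exactly the
    threshold is removed); self-loops and duplicates never enter; then
    vertices with degree < min_degree are removed in a single pass.
    """
    params = params or NetworkParams()
    genes = list(r.index)
    g = nx.Graph()
    rv = r.to_numpy(dtype=float)
    for i, a in enumerate(genes):
        for j in range(i + 1, len(genes)):
            if rv[i, j] > params.r_threshold:
                g.add_edge(a, genes[j], r=float(rv[i, j]), weight=1.0 - float(rv[i, j]))
    low = [v for v in g.nodes if g.degree(v) < params.min_degree]
    g.remove_nodes_from(low)
    if g.number_of_nodes() == 0:
        warnings.warn("graph is empty after correlation/degree filtering")
    for v in g.nodes:
        mean_beta = float(beta_means.get(v, np.nan))
        g.nodes[v]["mean_beta"] = mean_beta
        g.nodes[v]["size"] = mean_beta * params.size_scale
    return GeneNetwork(graph=g, params=params)


def minimum_spanning_tree(network: GeneNetwork) -> GeneNetwork:
    """Prim MST under edge weight 1 - r (spanning forest per component)."""
    g = network.graph
    if g.number_of_nodes() == 0:
        return GeneNetwork(graph=nx.Graph(), params=network.params)
    tree = nx.minimum_spanning_tree(g, weight="weight", algorithm="prim")
    for v in tree.nodes:
        tree.nodes[v].update(g.nodes[v])
    return GeneNetwork(graph=tree, params=network.params)


def communities(network: GeneNetwork) -> dict[str, int]:
    """Girvan-Newman communities at maximum modularity.

    Edges of maximal betweenness are removed iteratively (ties broken by
    the lexicographically smallest edge); among all partitions encountered
    the one with maximal (unweighted) modularity is returned, as community
    ids per gene numbered by sorted smallest member.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    work = nx.Graph()
    work.add_nodes_from(g.nodes)
    work.add_edges_from(g.edges)

    def partition(h):
        return [frozenset(c) for c in nx.connected_components(h)]

    best = partition(work)
    best_q = _modularity(g, best)
    while work.number_of_edges() > 0:
        eb = nx.edge_betweenness_centrality(work)
        max_val = max(eb.values())
        candidates = [e for e, v in eb.items() if np.isclose(v, max_val)]
        edge = min(tuple(sorted(e)) for e in candidates)
        work.remove_edge(*edge)
        part = partition(work)
        q = _modularity(g, part)
        if q > best_q + 1e-12:
            best_q, best = q, part
    ordered = sorted(best, key=lambda c: sorted(c)[0])
    assignment = {v: i + 1 for i, comm in enumerate(ordered) for v in comm}
    network.community = assignment
    return assignment


def _modularity(g: nx.Graph, partition) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    return nx.algorithms.community.modularity(g, partition, weight=None)


def augment_clusters(
    clusters: dict[str, list[str]],
    pool: list[str],
    train_eval,
    min_gain: float = 0.01,
    f1_target: float = 1.0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Greedy per-cluster gene augmentation guided by classifier F1.

    For each cluster, candidate genes from ``pool`` (ranked, e.g. by global
    forest importance) are appended one at a time; an addition is kept iff
    the macro-F1 of ``train_eval(gene_set)`` improves by at least
    ``min_gain``.  Augmentation stops when the pool is exhausted or every
    per-class F1 reaches ``f1_target``.  ``train_eval`` maps a gene list to
    a per-class F1 Series.  Returns the augmented clusters and a trace of
    every trial.
    """
    seen = set()
    for name, genes in clusters.items():
        overlap = seen & set(genes)
        if overlap:
            raise ValueError(f"clusters must be disjoint; duplicated: {sorted(overlap)}")
        seen |= set(genes)

    trace_rows = []
    augmented: dict[str, list[str]] = {}
    for name, genes in clusters.items():
        current = list(genes)
        try:
            f1 = train_eval(current)
        except Exception:
            raise RuntimeError(
                f"train_eval failed on cluster {name!r}; trace preserved"
            ) from None
        score = float(np.mean(f1))
        trace_rows.append(
            {"cluster": name, "candidate": None, "accepted": True,
             "macro_f1": score, "n_genes": len(current)}
        )
        for gene in pool:
            if gene in current:
                continue
            if np.all(np.asarray(f1) >= f1_target):
                break
            trial = current + [gene]
            trial_f1 = train_eval(trial)
            trial_score = float(np.mean(trial_f1))
            accepted = trial_score >= score + min_gain
            trace_rows.append(
                {"cluster": name, "candidate": gene, "accepted": accepted,
                 "macro_f1": trial_score, "n_genes": len(trial)}
            )
            if accepted:
                current, f1, score = trial, trial_f1, trial_score
        augmented[name] = current
    return augmented, pd.DataFrame(trace_rows)
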