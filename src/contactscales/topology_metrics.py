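"""Degree-mixing and cohesiveness metrics of residue graphs.

Assortativity is Newman's Pearson degree correlation over edges,

    r = [M^-1 sum_e j_e k_e - (M^-1 sum_e (j_e + k_e)/2)^2]
        / [M^-1 sum_e (j_e^2 + k_e^2)/2 - (M^-1 sum_e (j_e + k_e)/2)^2]

with j_e, k_e the endpoint degrees of edge e and M the edge count; each
edge is counted once.  When every endpoint degree is equal the denominator
vanishes and r is *undefined* (returned as NaN), not zero — degenerate
components are excluded from cohort averages rather than dragged to 0.

The clustering coefficient of node i is C_i = 2 e_i / (k_i (k_i - 1)),
the realized fraction of links among its neighbours; nodes of degree < 2
take C_i = 0 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .subnetworks import ResidueGraph, connected_components

__all__ = [
    "GraphMetrics",
    "ComponentMetrics",
    "assortativity",
    "clustering_coefficient",
    "graph_metrics",
]

_DENOM_TOL = 1e-12


@dataclass(frozen=True)
class GraphMetrics:
    """Summary metrics of one graph or component."""

    n_nodes: int
    n_edges: int
    r: float  # NaN when undefined
    mean_clustering: float
    mean_degree: float
    mean_edge_strength: float


@dataclass(frozen=True)
class ComponentMetrics:
    """Per-component metrics of a graph plus the assortative fraction.

    Only components with at least ``min_component_size`` nodes qualify;
    ``assortative_fraction`` is the share of qualifying components whose
    r is defined and strictly positive.
    """

    per_component: tuple[GraphMetrics, ...]
    min_component_size: int

    @property
    def n_components(self) -> int:
        return len(self.per_component)

    @property
    def assortative_fraction(self) -> float:
        if not self.per_component:
            return math.nan
        pos = sum(1 for m in self.per_component if m.r > 0)
        return pos / len(self.per_component)

    def mean(self, attr: str, skip_nan: bool = True) -> float:
        vals = np.array([getattr(m, attr) for m in self.per_component], dtype=float)
        if skip_nan:
            vals = vals[~np.isnan(vals)]
        return float(np.mean(vals)) if len(vals) else math.nan


def _degrees_per_edge(g: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    deg = dict(g.degree())
    j = np.array([deg[u] for u, _ in g.edges()], dtype=float)
    k = np.array([deg[v] for _, v in g.edges()], dtype=float)
    return j, k


def assortativity(g: ResidueGraph | nx.Graph) -> float:
    """Pearson degree correlation over edges; NaN when undefined."""
    graph = g.graph if isinstance(g, ResidueGraph) else g
    if graph.number_of_edges() == 0:
        raise ValueError("assortativity needs at least one edge")
    j, k = _degrees_per_edge(graph)
    mean_prod = np.mean(j * k)
    mean_sum = np.mean(0.5 * (j + k))
    mean_sq = np.mean(0.5 * (j * j + k * k))
    denom = mean_sq - mean_sum**2
    if denom <= _DENOM_TOL:
        return math.nan
    return float((mean_prod - mean_sum**2) / denom)


def clustering_coefficient(g: ResidueGraph | nx.Graph, node: int) -> float:
    """C_i = 2 e_i / (k_i (k_i - 1)); 0 for degree below 2."""
    graph = g.graph if isinstance(g, ResidueGraph) else g
    if node not in graph:
        raise KeyError(f"node {node} not in graph")
    neighbors = list(graph[node])
    k = len(neighbors)
    if k < 2:
        return 0.0
    e = sum(
        1
        for a in range(k)
        for b in range(a + 1, k)
        if graph.has_edge(neighbors[a], neighbors[b])
    )
    return 2.0 * e / (k * (k - 1))


def _component_metrics(sub: nx.Graph) -> GraphMetrics:
    n = sub.number_of_nodes()
    m = sub.number_of_edges()
    r = assortativity(sub) if m else math.nan
    mean_c = float(np.mean([clustering_coefficient(sub, v) for v in sub]))
    mean_k = 2.0 * m / n if n else math.nan
    strengths = [d.get("strength", math.nan) for _, _, d in sub.edges(data=True)]
    mean_s = float(np.mean(strengths)) if strengths else math.nan
    return GraphMetrics(
        n_nodes=n, n_edges=m, r=r,
        mean_clustering=mean_c, mean_degree=mean_k, mean_edge_strength=mean_s,
    )


def graph_metrics(g: ResidueGraph, min_component_size: int = 30) -> ComponentMetrics:
    """Metrics of every connected component of at least the given size.

    Subclusters below the size threshold (default 30 nodes) carry too few
    nodes for stable topology statistics and are excluded.
    """
    comps = connected_components(g)
    metrics = tuple(
        _component_metrics(g.graph.subgraph(c))
        for c in comps
        if len(c) >= min_component_size
    )
    return ComponentMetrics(per_component=metrics,
                            min_component_size=min_component_size)


def whole_graph_metrics(g: ResidueGraph) -> GraphMetrics:
    """Metrics of a graph taken as a whole (degree/strength summaries)."""
    return _component_metrics(g.graph)
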