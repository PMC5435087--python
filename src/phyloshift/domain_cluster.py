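"""Similarity-graph construction and Markov clustering (MCL).

Edge weights are -log10 E-values capped at 200; node degrees are capped by
keeping each node's heaviest edges and taking the symmetric union.  MCL
alternates expansion (matrix squaring) and inflation (entrywise power with
column renormalization) after a one-time pre-inflation step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DomainError, SelectionError

__all__ = [
    "SimilarityGraph",
    "Clustering",
    "build_graph",
    "mcl",
    "select_clustering",
    "inflation_sweep",
]

DEFAULT_INFLATIONS = (1.01, 1.05, 1.1, 1.15, 1.2, 1.4, 1.6, 1.8, 2.0, 3.0)


@dataclass
class SimilarityGraph:
    """Undirected weighted graph with weights in (0, cap]."""

    graph: nx.Graph
    cap: float = 200.0

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class Clustering:
    clusters: list[frozenset]
    inflation: float
    converged: bool = True
    selection_score: float = math.nan
    stochasticity_drift: float = 0.0  # max |column sum - 1| seen during MCL

    def labels(self) -> dict:
        out = {}
        for i, cluster in enumerate(self.clusters):
            for node in cluster:
                out[node] = i
        return out

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def build_graph(evalues, cap: float = 200.0, degree_cap: int = 280,
                min_e: float = 0.1) -> SimilarityGraph:
    """Build the similarity graph from (a, b, e-value) triples.

    Weight = min(-log10 e, cap); only edges with e <= min_e enter.  Degree
    capping keeps each node's ``degree_cap`` heaviest edges and retains the
    union, so mutual-or-either edges survive.  Self-edges are dropped with a
    warning; disconnection after capping also warns.
    """
    g = nx.Graph()
    dropped_self = 0
    for a, b, e in evalues:
        if e <= 0:
            raise DomainError(f"E-value must be > 0, got {e}")
        if a == b:
            dropped_self += 1
            continue
        if e > min_e:
            continue
        w = min(-math.log10(e), cap)
        if w <= 0:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    if dropped_self:
        warnings.warn(f"dropped {dropped_self} self-edge(s)", stacklevel=2)
    # degree capping: keep-heaviest per node, then symmetric union
    keep: set[frozenset] = set()
    for node in g.nodes:
        incident = sorted(
            g.edges(node, data="weight"), key=lambda e: -e[2])[:degree_cap]
        keep.update(frozenset((u, v)) for u, v, _ in incident)
    capped = nx.Graph()
    capped.add_nodes_from(g.nodes)
    for edge in keep:
        u, v = tuple(edge)
        capped.add_edge(u, v, weight=g[u][v]["weight"])
    if capped.number_of_nodes() and not nx.is_connected(capped):
        warnings.warn("similarity graph is not connected after capping",
                      stacklevel=2)
    return SimilarityGraph(capped, cap=cap)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    col = m.sum(axis=0, keepdims=True)
    col[col == 0] = 1.0
    return m / col


def _inflate(m: np.ndarray, power: float) -> np.ndarray:
    return _column_normalize(np.power(m, power))


def mcl(graph: SimilarityGraph, inflation: float, preinflation: float = 3.0,
        max_iter: int = 200, tol: float = 1e-6) -> Clustering:
    """Markov clustering at one inflation value.

    Self-loops are set to each node's max incident weight; the stochastic
    matrix is pre-inflated once, then expansion/inflation alternate until the
    max column change drops below ``tol``.  Non-convergence returns the last
    iterate with ``converged=False``.
    """
    if inflation <= 1.0:
        raise DomainError("inflation must be > 1")
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        raise DomainError("empty graph")
    if n == 1:
        return Clustering([frozenset(nodes)], inflation)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, w in graph.graph.edges(data="weight"):
        m[index[u], index[v]] = m[index[v], index[u]] = w
    loop = m.max(axis=1)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m = _column_normalize(m)
    m = _inflate(m, preinflation)
    converged = False
    drift = float(np.abs(m.sum(axis=0) - 1.0).max())
    for _ in range(max_iter):
        expanded = m @ m
        new = _inflate(expanded, inflation)
        drift = max(drift, float(np.abs(new.sum(axis=0) - 1.0).max()))
        if np.abs(new - m).max(axis=0).max() < tol:
            m = new
            converged = True
            break
        m = new
    if not converged:
        warnings.warn("MCL did not converge", stacklevel=2)
    # clusters: connected components of the attractor-overlap structure
    support = m > max(tol * 1e-2, 1e-9)
    overlap = nx.Graph()
    overlap.add_nodes_from(range(n))
    rows, cols = np.nonzero(support)
    overlap.add_edges_from(zip(rows, cols))
    clusters = [
        frozenset(nodes[i] for i in comp)
        for comp in nx.connected_components(overlap)
    ]
    clusters.sort(key=lambda c: sorted(map(str, c)))
    return Clustering(clusters, inflation, converged=converged,
                      stochasticity_drift=drift)


def select_clustering(clusterings: list[Clustering], annotated: set) -> Clustering:
    """Pick the clustering maximizing the mean number of annotated nodes per
    annotated-containing cluster; ties go to the lowest inflation."""
    if not annotated:
        raise DomainError("annotated set must be non-empty")
    best = None
    for clustering in clusterings:
        counts = [len(c & annotated) for c in clustering.clusters
                  if c & annotated]
        if not counts:
            continue
        score = float(np.mean(counts))
        clustering.selection_score = score
        key = (-score, clustering.inflation)
        if best is None or key < best[0]:
            best = (key, clustering)
    if best is None:
        raise SelectionError("no clustering contains an annotated node")
    return best[1]


def inflation_sweep(graph: SimilarityGraph,
                    inflations=DEFAULT_INFLATIONS,
                    preinflation: float = 3.0) -> list[Clustering]:
    return [mcl(graph, i, preinflation=preinflation) for i in inflations]
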