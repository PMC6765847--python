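"""Patient-patient similarity graph with a 0-1 edge threshold.

The node-link view links patients whose normalised test profiles are
similar under a selectable metric (cosine, Pearson, Spearman).  Because
the threshold slider runs 0-1, negative correlations are left raw and
simply never form edges.  Placement uses a seeded Fruchterman-Reingold
force-directed layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .data import NormalizedMatrix

__all__ = ["SimilarityGraph", "similarity_matrix", "build_graph", "force_layout"]

METRICS = ("cosine", "pearson", "spearman")


@dataclass
class SimilarityGraph:
    """Undirected graph: edge (a, b) present iff similarity(a, b) >= threshold."""

    node_ids: list
    metric: str
    threshold: float
    edges: dict = field(default_factory=dict)  # (id_a, id_b) a-before-b -> weight

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=float(w))
        return g


def _rowwise_pearson(x: np.ndarray) -> np.ndarray:
    """Correlation between rows across variables; constant rows get 0 with
    every other row and 1 with themselves."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    c = (xc @ xc.T) / np.outer(safe, safe)
    const = norms == 0
    c[const, :] = 0.0
    c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def similarity_matrix(u: NormalizedMatrix, metric: str = "cosine") -> np.ndarray:
    """Symmetric n x n similarity between patient rows.

    cosine: dot(a, b)/(|a||b|), zero vectors similar to nothing (0, even to
    themselves).  pearson: sample correlation of the two rows across
    variables.  spearman: Pearson on average-tied ranks.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = u.u
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 variables")
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        s = (x @ x.T) / np.outer(safe, safe)
        zero = norms == 0
        s[zero, :] = 0.0
        s[:, zero] = 0.0
        return np.clip(s, -1.0, 1.0)
    if metric == "pearson":
        return _rowwise_pearson(x)
    ranks = np.apply_along_axis(rankdata, 1, x)  # average ranks for ties
    return _rowwise_pearson(ranks)


def build_graph(
    sim: np.ndarray, threshold: float, node_ids=None, metric: str = "cosine"
) -> SimilarityGraph:
    """Threshold a similarity matrix into a graph.

    Edges are exactly the unordered pairs with similarity >= threshold;
    raising the threshold can only remove edges (nested graphs).
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    n = sim.shape[0]
    ids = list(node_ids) if node_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("node_ids length mismatch")
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                edges[(ids[i], ids[j])] = float(sim[i, j])
    return SimilarityGraph(ids, metric, threshold, edges)


def force_layout(
    graph: SimilarityGraph, iterations: int = 50, seed: int = 0
) -> dict:
    """Seeded Fruchterman-Reingold positions, id -> (x, y) ndarray.

    Deterministic for a fixed seed; similar (connected) patients end up
    closer together than unconnected ones.
    """
    g = graph.to_networkx()
    if g.number_of_nodes() == 0:
        raise ValueError("graph has no nodes")
    if g.number_of_nodes() == 1:
        return {graph.node_ids[0]: np.zeros(2)}
    pos = nx.spring_layout(g, iterations=iterations, seed=seed, weight="weight")
    return {k: np.asarray(v, dtype=float) for k, v in pos.items()}
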