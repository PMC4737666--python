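"""Graph distances and the high-dimensional node representation.

A weighted connectome is turned into a graph by defining the length of each
edge as the inverse of its coupling strength (a strongly coupled pair of
regions is "close").  All-pairs shortest-path lengths over those edge lengths
form the graph distance matrix; row ``i`` of that matrix is the coordinate
vector of node ``i`` in an n-dimensional Euclidean space, the representation
all embeddings start from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .io import WeightedConnectome

__all__ = [
    "EdgeLengthGraph",
    "GraphDistanceMatrix",
    "to_edge_lengths",
    "all_pairs_shortest_paths",
    "high_dim_representation",
    "representation_distance",
    "nodal_path_length",
]


@dataclass(frozen=True)
class EdgeLengthGraph:
    """Edge lengths 1/weight; ``inf`` marks an absent edge; diagonal is 0."""

    lengths: np.ndarray

    @property
    def n(self) -> int:
        return self.lengths.shape[0]

    def to_sparse(self) -> csr_matrix:
        finite = np.isfinite(self.lengths) & ~np.eye(self.n, dtype=bool)
        i, j = np.nonzero(finite)
        return csr_matrix((self.lengths[i, j], (i, j)), shape=(self.n, self.n))


@dataclass(frozen=True)
class GraphDistanceMatrix:
    """All-pairs shortest-path lengths (units: inverse coupling strength)."""

    dist: np.ndarray

    @property
    def n(self) -> int:
        return self.dist.shape[0]


def to_edge_lengths(c: WeightedConnectome) -> EdgeLengthGraph:
    """Edge length = 1 / weight for positive weights; zero weight means no edge."""
    with np.errstate(divide="ignore"):
        lengths = np.where(c.weights > 0, 1.0 / c.weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return EdgeLengthGraph(lengths)


def all_pairs_shortest_paths(g: EdgeLengthGraph) -> GraphDistanceMatrix:
    """Exact Dijkstra from every source over the edge-length graph.

    Disconnection is a hard error: every downstream stage (representation,
    embedding, cohesion statistics) assumes finite distances.
    """
    sparse = g.to_sparse()
    ncomp, comp = connected_components(sparse, directed=False)
    if ncomp > 1:
        a = np.flatnonzero(comp == comp[0])[:3]
        b = np.flatnonzero(comp != comp[0])[:3]
        pairs = [(int(i), int(j)) for i in a for j in b][:5]
        raise ValueError(
            f"graph is disconnected ({ncomp} components); unreachable node pairs "
            f"include {pairs}"
        )
    dist = dijkstra(sparse, directed=False)
    dist = (dist + dist.T) / 2.0  # kill last-bit asymmetry from summation order
    np.fill_diagonal(dist, 0.0)
    return GraphDistanceMatrix(dist)


def high_dim_representation(d: GraphDistanceMatrix) -> np.ndarray:
    """Node coordinates in n-space: row ``i`` is node i's vector of graph distances.

    Two nodes with similar coupling patterns to the rest of the network sit
    close together in this space regardless of their anatomic positions.
    """
    return d.dist.copy()


def representation_distance(r: np.ndarray, k: int, l: int) -> float:
    """Euclidean distance between representation rows ``k`` and ``l``."""
    n = r.shape[0]
    for idx in (k, l):
        if not 0 <= idx < n:
            raise IndexError(f"node index {idx} out of range [0, {n})")
    return float(np.linalg.norm(r[k] - r[l]))


def nodal_path_length(d: GraphDistanceMatrix) -> np.ndarray:
    """Mean graph distance of each node to all others (self excluded).

    Lower values mark nodes that communicate efficiently with the whole
    network.
    """
    n = d.n
    if n < 2:
        raise ValueError("nodal path length needs at least 2 nodes")
    return d.dist.sum(axis=1) / (n - 1)
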