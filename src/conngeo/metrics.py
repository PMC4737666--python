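"""Nodal graph metrics, the centrality validation regression, and the
embedding-dimension sweep.

The metrics (strength, Onnela weighted clustering, nodal path length,
betweenness, embeddedness) drive targeted node-removal orderings and the
validation analyses: a node's mean graph distance to the rest of the network
should predict how far from the embedding center it lands, and the quality of
that linear relation (r²) measures how faithfully an embedding space captures
network centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .embedding import AUTO, Embedding, distance_to_center, isomap
from .graph import EdgeLengthGraph, GraphDistanceMatrix
from .io import NodeTable, WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "NodalMetrics",
    "ValidationResult",
    "DimensionSweepResult",
    "nodal_strength",
    "clustering_coefficient",
    "betweenness_centrality",
    "embeddedness_score",
    "compute_nodal_metrics",
    "centrality_validation",
    "rank_by_center_distance",
    "dimension_sweep",
]


@dataclass(frozen=True)
class NodalMetrics:
    strength: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    betweenness: np.ndarray
    embeddedness: np.ndarray


@dataclass(frozen=True)
class ValidationResult:
    """OLS of distance-to-center on nodal path length in one space."""

    r_squared: float
    slope: float
    intercept: float
    space: str


@dataclass(frozen=True)
class DimensionSweepResult:
    dims: tuple[int, ...]
    rmse: tuple[float, ...]
    k_used: tuple[int, ...]


def nodal_strength(c: WeightedConnectome) -> np.ndarray:
    """Sum of incident edge weights per node."""
    return c.weights.sum(axis=1)


def clustering_coefficient(c: WeightedConnectome) -> np.ndarray:
    """Onnela weighted clustering coefficient, in [0, 1].

    Weights are first scaled by the network maximum, ``ŵ = w / max(w)``;
    node i's coefficient averages the geometric-mean intensity of the
    triangles through i over the ``k_i (k_i − 1)`` pairs of its neighbors
    (``k_i`` = binary degree).  Nodes with fewer than two neighbors score 0.
    """
    w = c.weights
    w_hat = w / w.max()
    cube_root = np.cbrt(w_hat)
    triangles = np.diagonal(cube_root @ cube_root @ cube_root)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(c.n)
    mask = denom > 0
    out[mask] = triangles[mask] / denom[mask]
    return out


def betweenness_centrality(g: EdgeLengthGraph) -> np.ndarray:
    """Unnormalized node betweenness over shortest paths on edge lengths.

    Endpoints are excluded; equal-length path multiplicities split
    fractionally (Brandes accumulation).
    """
    n = g.n
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    finite = np.isfinite(g.lengths) & ~np.eye(n, dtype=bool)
    ii, jj = np.nonzero(np.triu(finite, k=1))
    graph.add_weighted_edges_from(
        (int(i), int(j), float(g.lengths[i, j])) for i, j in zip(ii, jj)
    )
    if not nx.is_connected(graph):
        raise ValueError("betweenness requires a connected graph")
    bc = nx.betweenness_centrality(graph, weight="weight", normalized=False, endpoints=False)
    return np.array([bc[i] for i in range(n)])


def embeddedness_score(
    c: WeightedConnectome,
    d: GraphDistanceMatrix,
    ranking: np.ndarray | None = None,
) -> np.ndarray:
    """Ratio of nodal efficiency to the information-transfer decay rate.

    This is a documented proxy: the numerator is nodal efficiency
    ``E(i) = mean_{j≠i} 1/dist(i, j)``; the denominator is the decay rate
    ``λ(i)``, the negative slope of ``log(mean inverse graph distance to the
    h-hop shell)`` against hop count ``h`` on the binarized graph.  A node
    whose shell efficiency does not decay (λ ≤ 0, or fewer than two shells)
    gets ``+inf`` and is logged.  A caller-supplied per-node ``ranking``
    bypasses the proxy entirely and is returned unchanged.
    """
    if ranking is not None:
        ranking = np.asarray(ranking, dtype=float)
        if ranking.shape != (c.n,):
            raise ValueError(f"ranking must have shape ({c.n},)")
        return ranking
    n = c.n
    dist = d.dist
    inv = np.zeros_like(dist)
    off = ~np.eye(n, dtype=bool)
    inv[off] = 1.0 / dist[off]
    efficiency = inv.sum(axis=1) / (n - 1)

    hops = shortest_path((c.weights > 0).astype(float), unweighted=True, directed=False)
    scores = np.empty(n)
    for i in range(n):
        h_max = int(hops[i, off[i]].max())
        shell_eff = []
        for h in range(1, h_max + 1):
            shell = hops[i] == h
            if shell.any():
                shell_eff.append(inv[i, shell].mean())
        if len(shell_eff) < 2:
            logger.info("embeddedness: node %d has a single hop shell; score set to inf", i)
            scores[i] = np.inf
            continue
        hs = np.arange(1, len(shell_eff) + 1, dtype=float)
        slope = np.polyfit(hs, np.log(shell_eff), 1)[0]
        lam = -slope
        if lam <= 0:
            logger.info("embeddedness: node %d shows no decay (λ=%g); score set to inf", i, lam)
            scores[i] = np.inf
        else:
            scores[i] = efficiency[i] / lam
    return scores


def compute_nodal_metrics(c: WeightedConnectome) -> NodalMetrics:
    """All five nodal metrics from one connectome (distances computed once)."""
    from .graph import all_pairs_shortest_paths, nodal_path_length, to_edge_lengths

    g = to_edge_lengths(c)
    d = all_pairs_shortest_paths(g)
    return NodalMetrics(
        strength=nodal_strength(c),
        clustering=clustering_coefficient(c),
        path_length=nodal_path_length(d),
        betweenness=betweenness_centrality(g),
        embeddedness=embeddedness_score(c, d),
    )


def _center_distances(values) -> np.ndarray:
    if isinstance(values, Embedding):
        return distance_to_center(values)
    coords = np.asarray(values, dtype=float)
    return np.linalg.norm(coords - coords.mean(axis=0), axis=1)


def centrality_validation(values, npl: np.ndarray, space: str = "") -> ValidationResult:
    """Regress distance-to-center on nodal path length; report r², slope, intercept.

    ``values`` is either an :class:`Embedding` or a coordinate matrix (e.g.
    anatomic centroids, whose center is the mean coordinate of all regions).
    High r² means the space arranges nodes so that efficient communicators
    sit near the center.
    """
    npl = np.asarray(npl, dtype=float)
    dist = _center_distances(values)
    if dist.shape != npl.shape:
        raise ValueError("coordinate rows and nodal path length lengths differ")
    if npl.size < 3:
        raise ValueError("need at least 3 nodes for a correlation")
    if npl.std() == 0 or dist.std() == 0:
        raise ValueError("degenerate correlation: constant input")
    fit = stats.linregress(npl, dist)
    return ValidationResult(float(fit.rvalue**2), float(fit.slope), float(fit.intercept), space)


def rank_by_center_distance(e: Embedding, t: NodeTable | None = None):
    """Nodes sorted by ascending distance to the embedding center.

    Returns a DataFrame with label, distance, rank (0 = most central) and,
    when available, rich-club and lobe annotations.  Ties break
    alphabetically by label.
    """
    import pandas as pd

    dist = distance_to_center(e)
    labels = list(t.label) if t is not None else [f"N{i:03d}" for i in range(e.n)]
    if len(labels) != e.n:
        raise ValueError("node table and embedding sizes differ")
    df = pd.DataFrame({"label": labels, "distance": dist})
    if t is not None and t.rich_club is not None:
        df["rich_club"] = t.rich_club
    if t is not None and t.lobe is not None:
        df["lobe"] = list(t.lobe)
    df = df.sort_values(["distance", "label"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(len(df))
    return df


def dimension_sweep(
    r: np.ndarray,
    npl: np.ndarray,
    dims=range(1, 9),
    k: int | str = AUTO,
    k_start: int = 3,
) -> DimensionSweepResult:
    """RMSE of center distances not explained by nodal path length, per dimension.

    For each target dimension the representation is re-embedded with Isomap,
    the distance-to-center is regressed on nodal path length (OLS with
    intercept), and the root mean squared residual is recorded.  A flat tail
    in the RMSE curve indicates the intrinsic dimensionality has been
    reached.
    """
    npl = np.asarray(npl, dtype=float)
    dims = tuple(int(d) for d in dims)
    rmses: list[float] = []
    ks: list[int] = []
    for d in dims:
        e = isomap(r, d, k=k, k_start=k_start)
        dist = distance_to_center(e)
        fit = stats.linregress(npl, dist)
        resid = dist - (fit.slope * npl + fit.intercept)
        rmses.append(float(np.sqrt(np.mean(resid**2))))
        ks.append(int(e.k_used))
    return DimensionSweepResult(dims, tuple(rmses), tuple(ks))
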