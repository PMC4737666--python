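"""Model/Results interface for connectome intrinsic geometry.

:class:`IntrinsicGeometry` holds a validated connectome (plus optional node
metadata) and lazily derives the objects every analysis shares: edge lengths,
the graph distance matrix, the n-dimensional node representation, and nodal
path lengths.  Calling :meth:`IntrinsicGeometry.fit` embeds the
representation with classical MDS or Isomap and returns an
:class:`IntrinsicGeometryResults` carrying the coordinates, the retained
spectrum, fit diagnostics (residual variance, centrality-validation r²), and
a ``summary()`` table.  Lesion simulations and the dimension sweep hang off
the model; ranking tables and JSON export hang off the results.

Example
-------
>>> from conngeo import IntrinsicGeometry, synthetic
>>> c, t = synthetic.make_modular_connectome()
>>> res = IntrinsicGeometry(c, t).fit(method="isomap", dim=3)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import embedding as _embedding
from . import graph as _graph
from . import lesion as _lesion
from . import metrics as _metrics
from .embedding import AUTO, Embedding
from .io import NodeTable, WeightedConnectome, export_embedding_json, read_connectome, read_node_table

__all__ = ["IntrinsicGeometry", "IntrinsicGeometryResults"]


class IntrinsicGeometry:
    """The intrinsic-geometry model of a weighted connectome."""

    def __init__(self, connectome: WeightedConnectome, nodes: NodeTable | None = None):
        if nodes is not None:
            nodes.require_match(connectome)
        self.connectome = connectome
        self.nodes = nodes

    @classmethod
    def from_files(cls, matrix_path, nodes_path=None) -> "IntrinsicGeometry":
        nodes = read_node_table(nodes_path) if nodes_path else None
        return cls(read_connectome(matrix_path), nodes)

    # -- shared derived objects, computed once -----------------------------
    @cached_property
    def edge_lengths(self) -> _graph.EdgeLengthGraph:
        return _graph.to_edge_lengths(self.connectome)

    @cached_property
    def graph_distances(self) -> _graph.GraphDistanceMatrix:
        return _graph.all_pairs_shortest_paths(self.edge_lengths)

    @cached_property
    def representation(self) -> np.ndarray:
        """n×n high-dimensional node coordinates (graph-distance rows)."""
        return _graph.high_dim_representation(self.graph_distances)

    @cached_property
    def nodal_path_length(self) -> np.ndarray:
        return _graph.nodal_path_length(self.graph_distances)

    @property
    def n(self) -> int:
        return self.connectome.n

    # -- fitting ------------------------------------------------------------
    def fit(self, method: str = "isomap", dim: int = 3, k: int | str = AUTO,
            k_start: int = 3) -> "IntrinsicGeometryResults":
        """Embed the representation into ``dim`` dimensions.

        ``method='mds'`` applies classical MDS to the Euclidean distances
        between representation rows; ``method='isomap'`` routes those
        distances through the kNN geodesic graph first.
        """
        from scipy.spatial.distance import cdist

        if method == "mds":
            emb = _embedding.classical_mds(cdist(self.representation, self.representation), dim)
        elif method == "isomap":
            emb = _embedding.isomap(self.representation, dim, k=k, k_start=k_start)
        else:
            raise ValueError(f"unknown method {method!r}; use 'mds' or 'isomap'")
        return IntrinsicGeometryResults(self, emb)

    # -- simulations ---------------------------------------------------------
    def lesion(self, scheme: str, fraction: float = 0.215, dim: int = 3,
               ranking=None, seed=None) -> _lesion.RemovalResult:
        return _lesion.targeted_removal(self.connectome, scheme, fraction,
                                        embed_dim=dim, table=self.nodes,
                                        ranking=ranking, seed=seed)

    def random_removal(self, fraction: float = 0.215, trials: int = 1000,
                       seed: int = 0, dim: int = 3) -> _lesion.RandomRemovalDistribution:
        return _lesion.random_removal_distribution(self.connectome, fraction, trials,
                                                   seed, embed_dim=dim)

    def dimension_sweep(self, dims=range(1, 9)) -> _metrics.DimensionSweepResult:
        return _metrics.dimension_sweep(self.representation, self.nodal_path_length, dims)

    def nodal_metrics(self) -> _metrics.NodalMetrics:
        return _metrics.compute_nodal_metrics(self.connectome)


@dataclass(frozen=True)
class IntrinsicGeometryResults:
    """A fitted low-dimensional embedding with its diagnostics."""

    model: IntrinsicGeometry
    embedding: Embedding

    @property
    def coords(self) -> np.ndarray:
        return self.embedding.coords

    @property
    def method(self) -> str:
        return self.embedding.method

    @cached_property
    def distance_to_center(self) -> np.ndarray:
        return _embedding.distance_to_center(self.embedding)

    @property
    def dbar(self) -> float:
        """Cohesion: mean distance of embedded nodes to the embedding center."""
        return float(self.distance_to_center.mean())

    @property
    def residual_variance(self) -> float:
        """1 − r² between representation distances and embedded distances."""
        from scipy.spatial.distance import cdist

        rep = self.model.representation
        return _embedding.residual_variance(cdist(rep, rep), self.embedding)

    @property
    def validation(self) -> _metrics.ValidationResult:
        """OLS of distance-to-center on nodal path length in this embedding."""
        return _metrics.centrality_validation(self.embedding,
                                              self.model.nodal_path_length,
                                              space=self.method)

    def rank_table(self):
        """Nodes ordered by ascending distance to the embedding center."""
        return _metrics.rank_by_center_distance(self.embedding, self.model.nodes)

    def export_json(self, path) -> None:
        export_embedding_json(self.embedding, self.model.nodes, self.model.connectome, path)

    def plot(self, ax=None, color_by: str = "lobe"):
        """3-D scatter of the embedding, colored by lobe or rich-club flag."""
        import matplotlib.pyplot as plt

        if self.embedding.dim != 3:
            raise ValueError("plotting expects a 3-D embedding")
        if ax is None:
            fig = plt.figure()
            ax = fig.add_subplot(projection="3d")
        x, y, z = self.coords.T
        nodes = self.model.nodes
        if nodes is not None and color_by == "lobe" and nodes.lobe is not None:
            for lobe in sorted(set(nodes.lobe)):
                m = np.array([l == lobe for l in nodes.lobe])
                ax.scatter(x[m], y[m], z[m], s=12, label=lobe)
            ax.legend(fontsize="small")
        elif nodes is not None and color_by == "rich_club" and nodes.rich_club is not None:
            m = nodes.rich_club
            ax.scatter(x[~m], y[~m], z[~m], s=10, c="lightgray")
            ax.scatter(x[m], y[m], z[m], s=16, c="crimson", label="rich club")
            ax.legend(fontsize="small")
        else:
            ax.scatter(x, y, z, s=12)
        ax.set_title(f"{self.method} embedding (n={self.embedding.n})")
        return ax

    def summary(self) -> str:
        """Human-readable fit report."""
        e = self.embedding
        v = self.validation
        lam = ", ".join(f"{x:.4g}" for x in e.eigenvalues)
        lines = [
            "Intrinsic geometry fit",
            "=" * 58,
            f"nodes:                 {e.n}",
            f"method:                {e.method}",
            f"target dimension:      {e.dim}",
        ]
        if e.k_used is not None:
            lines.append(f"neighborhood k used:   {e.k_used}")
        if e.n_negative_clamped:
            lines.append(f"eigenvalues clamped:   {e.n_negative_clamped}")
        lines += [
            f"retained eigenvalues:  [{lam}]",
            f"residual variance:     {self.residual_variance:.4f}",
            f"cohesion d-bar:        {self.dbar:.4f}",
            "-" * 58,
            "distance-to-center ~ nodal path length (OLS)",
            f"  r^2:                 {v.r_squared:.4f}",
            f"  slope:               {v.slope:.4f}",
            f"  intercept:           {v.intercept:.4f}",
        ]
        return "\n".join(lines)
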