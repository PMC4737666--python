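"""Targeted and Monte-Carlo random node removal scored by embedding cohesion.

Removing a set of nodes, recomputing graph distances and the Isomap embedding
on the survivors, and measuring d̄ — the mean Euclidean distance from the
embedded nodes to the embedding center — quantifies how much the network's
intrinsic geometry depends on those nodes.  Removal of structurally central
nodes (e.g. a rich club) inflates surviving graph distances and therefore d̄,
while removals that only prune the periphery barely move it.

Each removal is treated as a brand-new topology: distances and the embedding
are recomputed from scratch on the survivor network rather than projected
from the original embedding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from . import metrics as _metrics
from .embedding import AUTO, Embedding, isomap
from .graph import all_pairs_shortest_paths, high_dim_representation, to_edge_lengths
from .io import NodeTable, WeightedConnectome

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "RemovalResult",
    "RandomRemovalDistribution",
    "remove_nodes",
    "dbar",
    "normalized_dbar",
    "removal_count",
    "scheme_ordering",
    "targeted_removal",
    "random_removal_distribution",
]

SCHEMES = (
    "random",
    "rich_club",
    "strength",
    "clustering",
    "path_length",
    "betweenness",
    "embeddedness",
    "subcortical",
    "custom",
)


@dataclass(frozen=True)
class RemovalResult:
    scheme: str
    removed: tuple[str, ...]
    fraction: float
    dbar_raw: float
    dbar_normalized: float
    embedding: Embedding
    survivor: WeightedConnectome


@dataclass(frozen=True)
class RandomRemovalDistribution:
    trials: int
    dbar_values: np.ndarray
    mean: float
    interval: tuple[float, float]  # (5th, 95th) percentiles
    seed: int
    redraws: int  # disconnecting draws that had to be redrawn


def removal_count(fraction: float, n: int) -> int:
    """round(fraction·n), rounding half away from zero for platform determinism."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    return int(math.floor(fraction * n + 0.5))


def remove_nodes(c: WeightedConnectome, removed) -> WeightedConnectome:
    """Survivor connectome after deleting ``removed`` (labels or indices).

    Pure submatrix extraction — surviving edge weights are untouched.  An
    error is raised if the survivor graph is disconnected (the Monte-Carlo
    driver catches this and redraws).
    """
    idx = sorted({c.index_of(r) if isinstance(r, str) else int(r) for r in removed})
    if not idx:
        raise ValueError("removal set is empty")
    if len(idx) >= c.n:
        raise ValueError("cannot remove every node")
    keep = np.setdiff1d(np.arange(c.n), idx)
    sub = c.weights[np.ix_(keep, keep)]
    ncomp, _ = connected_components((sub > 0).astype(np.int8), directed=False)
    if ncomp > 1 or (sub.sum(axis=1) == 0).any():
        raise ValueError(f"removal disconnects the survivor graph ({ncomp} components)")
    return WeightedConnectome(sub, tuple(c.labels[i] for i in keep))


def dbar(e: Embedding) -> float:
    """Mean Euclidean distance of embedded nodes to the embedding center."""
    from .embedding import distance_to_center

    return float(distance_to_center(e).mean())


def normalized_dbar(d: float, c_surviving: WeightedConnectome) -> float:
    """d̄ scaled by the surviving network's mean coupling strength.

    The multiplier is the mean over all off-diagonal node pairs, zeros
    (unconnected pairs) included; it makes removals comparable across
    networks whose surviving weight mass differs.
    """
    if d < 0:
        raise ValueError("d̄ must be nonnegative")
    n = c_surviving.n
    mean_weight = c_surviving.weights.sum() / (n * (n - 1))
    return float(d * mean_weight)


def _embed_survivors(c: WeightedConnectome, embed_dim: int, k_start: int) -> Embedding:
    d = all_pairs_shortest_paths(to_edge_lengths(c))
    return isomap(high_dim_representation(d), embed_dim, k=AUTO, k_start=k_start)


def scheme_ordering(
    c: WeightedConnectome,
    scheme: str,
    table: NodeTable | None = None,
    ranking: np.ndarray | None = None,
) -> np.ndarray:
    """Node indices in removal-priority order for a targeted scheme.

    Metric schemes sort by the metric in the conventional attack direction
    (strength and betweenness and embeddedness: highest first; clustering and
    nodal path length: lowest first).  Flag schemes (``rich_club``,
    ``subcortical``) put flagged nodes first, alphabetically by label;
    ``custom`` sorts a caller-supplied ranking descending.  Ties in metric
    schemes break by node index (stable sort).
    """
    n = c.n
    if scheme in ("strength", "clustering", "path_length", "betweenness", "embeddedness"):
        nm = {
            "strength": lambda: _metrics.nodal_strength(c),
            "clustering": lambda: _metrics.clustering_coefficient(c),
            "path_length": lambda: _pl(c),
            "betweenness": lambda: _metrics.betweenness_centrality(to_edge_lengths(c)),
            "embeddedness": lambda: _emb(c),
        }[scheme]()
        ascending = scheme in ("clustering", "path_length")
        key = nm if ascending else -nm
        return np.argsort(key, kind="stable")
    if scheme in ("rich_club", "subcortical"):
        if table is None:
            raise ValueError(f"scheme {scheme!r} needs a node table")
        if scheme == "rich_club":
            if table.rich_club is None:
                raise ValueError("scheme 'rich_club' needs a rich_club flag column")
            flags = table.rich_club
        else:
            if table.lobe is None:
                raise ValueError("scheme 'subcortical' needs a lobe column")
            flags = np.array([l.lower() == "subcortical" for l in table.lobe])
        labels = np.asarray(table.label)
        order = np.lexsort((labels, ~flags))  # flagged first, then by label
        return order
    if scheme == "custom":
        if ranking is None:
            raise ValueError("scheme 'custom' needs a ranking vector")
        ranking = np.asarray(ranking, dtype=float)
        if ranking.shape != (n,):
            raise ValueError(f"ranking must have shape ({n},)")
        return np.argsort(-ranking, kind="stable")
    raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {SCHEMES}")


def _pl(c: WeightedConnectome) -> np.ndarray:
    from .graph import nodal_path_length

    return nodal_path_length(all_pairs_shortest_paths(to_edge_lengths(c)))


def _emb(c: WeightedConnectome) -> np.ndarray:
    return _metrics.embeddedness_score(c, all_pairs_shortest_paths(to_edge_lengths(c)))


def targeted_removal(
    c: WeightedConnectome,
    scheme: str,
    fraction: float,
    embed_dim: int = 3,
    table: NodeTable | None = None,
    ranking: np.ndarray | None = None,
    seed: int | None = None,
    k_start: int = 3,
) -> RemovalResult:
    """Remove the top ``round(fraction·n)`` nodes of a scheme's ordering and
    re-embed the survivors.

    ``scheme='random'`` draws one uniformly random subset (seeded).  Returns
    the raw and normalized cohesion statistic d̄ together with the survivor
    embedding.
    """
    m = removal_count(fraction, c.n)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(c.n)
    else:
        order = scheme_ordering(c, scheme, table=table, ranking=ranking)
    removed_idx = order[:m]
    survivor = remove_nodes(c, removed_idx)
    e = _embed_survivors(survivor, embed_dim, k_start)
    d = dbar(e)
    return RemovalResult(
        scheme=scheme,
        removed=tuple(c.labels[i] for i in sorted(removed_idx)),
        fraction=fraction,
        dbar_raw=d,
        dbar_normalized=normalized_dbar(d, survivor),
        embedding=e,
        survivor=survivor,
    )


def random_removal_distribution(
    c: WeightedConnectome,
    fraction: float,
    trials: int,
    seed: int,
    embed_dim: int = 3,
    k_start: int = 3,
    max_redraws: int = 100,
) -> RandomRemovalDistribution:
    """Monte-Carlo distribution of d̄ under uniform random node removal.

    Each trial draws a subset of size ``round(fraction·n)`` whose removal
    keeps the survivors connected (disconnecting draws are redrawn, up to
    ``max_redraws`` consecutive failures), recomputes the survivor Isomap
    embedding, and records d̄.  Fully reproducible from ``seed``.
    """
    if trials < 1:
        raise ValueError("need at least 1 trial")
    m = removal_count(fraction, c.n)
    rng = np.random.default_rng(seed)
    values = np.empty(trials)
    total_redraws = 0
    for t in range(trials):
        for attempt in range(max_redraws):
            subset = rng.choice(c.n, size=m, replace=False)
            try:
                survivor = remove_nodes(c, subset)
                break
            except ValueError:
                total_redraws += 1
        else:
            raise ValueError(
                f"network too fragile for fraction {fraction}: "
                f"{max_redraws} consecutive disconnecting draws"
            )
        values[t] = dbar(_embed_survivors(survivor, embed_dim, k_start))
    if total_redraws:
        logger.info("random removal: %d disconnecting draw(s) redrawn", total_redraws)
    lo, hi = np.percentile(values, [5, 95])
    return RandomRemovalDistribution(
        trials=trials,
        dbar_values=values,
        mean=float(values.mean()),
        interval=(float(lo), float(hi)),
        seed=seed,
        redraws=total_redraws,
    )
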