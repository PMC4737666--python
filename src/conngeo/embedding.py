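"""Low-dimensional embeddings of the node representation.

Two routes from the n-dimensional graph-distance representation down to a
handful of coordinates:

* **classical (Torgerson) MDS** — eigendecomposition of the double-centered
  squared-distance matrix; linear, global, deterministic.
* **Isomap** — geodesic distances over a k-nearest-neighbor graph followed by
  classical MDS, so the final step of both methods is identical and the
  comparison isolates the geodesic-vs-straight-line question.  The
  neighborhood size can grow automatically until the kNN graph is connected.

Both produce an :class:`Embedding` whose centroid sits at the origin, so a
node's distance to the embedding center is a meaningful centrality readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding",
    "classical_mds",
    "min_connected_k",
    "isomap",
    "distance_to_center",
    "residual_variance",
]

AUTO = "auto"


@dataclass(frozen=True)
class Embedding:
    """n×d coordinates with the retained spectrum and provenance."""

    coords: np.ndarray
    method: str  # "mds" or "isomap"
    eigenvalues: np.ndarray  # the d retained spectral values, descending
    k_used: int | None = None  # Isomap neighborhood size actually used
    n_negative_clamped: int = 0  # retained eigenvalues clamped up to 0

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


def _validate_distance_matrix(dm: np.ndarray) -> np.ndarray:
    dm = np.asarray(dm, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dm.shape}")
    if np.abs(dm - dm.T).max() > 1e-9:
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(dm) != 0).any():
        raise ValueError("distance matrix must have a zero diagonal")
    if (dm < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    return dm


def classical_mds(dm: np.ndarray, d: int, method_name: str = "mds") -> Embedding:
    """Torgerson MDS: embed ``n`` points from their pairwise distance matrix.

    Double-centers the squared distances, ``B = -1/2 J (dm∘dm) J`` with
    ``J = I - 11ᵀ/n``, and keeps the top ``d`` eigenpairs.  Negative retained
    eigenvalues (non-Euclidean input, as graph distances may be) are clamped
    to zero and counted.  Axis signs follow a fixed convention — the
    largest-magnitude coordinate on each axis is positive — so outputs are
    reproducible across platforms.
    """
    dm = _validate_distance_matrix(dm)
    n = dm.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"target dimension {d} outside [1, {n - 1}]")
    sq = dm * dm
    row = sq.mean(axis=1, keepdims=True)
    col = sq.mean(axis=0, keepdims=True)
    b = -0.5 * (sq - row - col + sq.mean())
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:d]
    lam = eigvals[order]
    vecs = eigvecs[:, order]
    clamped = int((lam < 0).sum())
    if clamped:
        logger.info("classical_mds: clamped %d negative eigenvalue(s) to 0", clamped)
    lam_pos = np.clip(lam, 0.0, None)
    coords = vecs * np.sqrt(lam_pos)
    # deterministic sign: flip each axis so its largest-|entry| is positive
    for a in range(d):
        col_a = coords[:, a]
        if col_a.any() and col_a[np.argmax(np.abs(col_a))] < 0:
            coords[:, a] = -col_a
    coords = coords - coords.mean(axis=0)  # enforce centroid invariant exactly
    return Embedding(coords, method_name, lam_pos, None, clamped)


def _knn_graph(euclid: np.ndarray, k: int) -> csr_matrix:
    """Union-symmetrized kNN graph; ties among equidistant candidates go to
    the lower node index (stable argsort)."""
    m = euclid.shape[0]
    e = euclid.copy()
    np.fill_diagonal(e, np.inf)
    nbrs = np.argsort(e, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(m), k)
    cols = nbrs.ravel()
    data = e[rows, cols]
    g = csr_matrix((data, (rows, cols)), shape=(m, m))
    return g.maximum(g.T)  # union symmetrization


def min_connected_k(points: np.ndarray, k_start: int = 3) -> int:
    """Smallest ``k >= k_start`` whose union kNN graph is one connected component."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = points.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points")
    euclid = cdist(points, points)
    for k in range(max(1, k_start), m):
        ncomp, _ = connected_components(_knn_graph(euclid, k), directed=False)
        if ncomp == 1:
            return k
    return m - 1


def isomap(points: np.ndarray, d: int, k: int | str = AUTO, k_start: int = 3) -> Embedding:
    """Nonlinear embedding via geodesic distances on the kNN graph.

    ``points`` are row coordinates (typically the graph-distance
    representation).  With ``k='auto'`` the neighborhood grows from
    ``k_start`` until the graph connects, mirroring the iterative
    neighborhood growth used to keep every region on the manifold.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if not 1 <= d <= n - 1:
        raise ValueError(f"target dimension {d} outside [1, {n - 1}]")
    euclid = cdist(points, points)
    if k == AUTO:
        k_used = min_connected_k(points, k_start=k_start)
    else:
        k_used = int(k)
        if not 1 <= k_used <= n - 1:
            raise ValueError(f"k={k_used} outside [1, {n - 1}]")
        ncomp, _ = connected_components(_knn_graph(euclid, k_used), directed=False)
        if ncomp > 1:
            raise ValueError(
                f"kNN graph with k={k_used} is disconnected ({ncomp} components); "
                "use k='auto' to grow the neighborhood until it connects"
            )
    geo = dijkstra(_knn_graph(euclid, k_used), directed=False)
    geo = (geo + geo.T) / 2.0
    np.fill_diagonal(geo, 0.0)
    emb = classical_mds(geo, d, method_name="isomap")
    return Embedding(emb.coords, "isomap", emb.eigenvalues, k_used, emb.n_negative_clamped)


def distance_to_center(e: Embedding) -> np.ndarray:
    """Per-node Euclidean distance to the embedding centroid."""
    coords = e.coords - e.coords.mean(axis=0)
    return np.linalg.norm(coords, axis=1)


def residual_variance(dm_input: np.ndarray, e: Embedding) -> float:
    """1 − r² between the input distances and the embedded distances.

    The standard Isomap fit diagnostic: 0 means the embedding reproduces the
    input distances perfectly (up to an affine relation), 1 means no linear
    relation at all.
    """
    dm_input = np.asarray(dm_input, dtype=float)
    if dm_input.shape[0] != e.n:
        raise ValueError("distance matrix and embedding sizes differ")
    iu = np.triu_indices(e.n, k=1)
    x = dm_input[iu]
    y = cdist(e.coords, e.coords)[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (constant) distances: residual variance undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r * r)
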