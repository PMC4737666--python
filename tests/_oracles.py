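"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by dynamic programming over intermediates."""
    d = lengths.copy().astype(float)
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def enumerate_betweenness(lengths: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Exhaustive shortest-path enumeration (endpoints excluded, fractional ties)."""
    n = lengths.shape[0]
    dist = floyd_warshall(lengths)
    finite = np.isfinite(lengths)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths: list[list[int]] = []

            def extend(node, acc):
                if node == t:
                    paths.append(acc)
                    return
                for v in range(n):
                    if v == node or not finite[node, v]:
                        continue
                    # edge (node, v) lies on a shortest s-t path through acc
                    if abs(dist[s, node] + lengths[node, v] + dist[v, t] - dist[s, t]) < tol:
                        if v not in acc:
                            extend(v, acc + [v])

            extend(s, [s])
            if not paths:
                continue
            share = 1.0 / len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += share
    return bc / 2.0  # undirected: each pair counted twice


def procrustes_error(a: np.ndarray, b: np.ndarray) -> float:
    """Relative Frobenius residual after optimal rotation/reflection (no scaling)."""
    from scipy.linalg import orthogonal_procrustes

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    r, _ = orthogonal_procrustes(a, b)
    return float(np.linalg.norm(a @ r - b) / max(np.linalg.norm(b), 1e-300))
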