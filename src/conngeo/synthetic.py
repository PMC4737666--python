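"""Synthetic inputs with the structural features the pipeline assumes.

Three generators:

* modular weighted connectomes with a planted, densely interconnected
  connector core (a "rich club"), heavy-tailed positive weights, zero
  diagonal, and no isolated nodes — plus matching anatomic coordinates that
  are deliberately decoupled from the topology, so the dissociation between
  anatomic position and intrinsic geometry is testable;
* the classic Swiss-roll point cloud with its true 2-D manifold coordinates;
* random Voronoi label volumes for the parcellation algorithm.

Every generator is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io import NodeTable, WeightedConnectome
from .parcellation import LabelVolume

__all__ = [
    "SyntheticSpec",
    "DEFAULT_SPEC",
    "make_modular_connectome",
    "make_swiss_roll",
    "make_label_volume",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-core modular connectome generator.

    The generated network emulates a coarse structural brain network:

    * a few *communities* (lobes) whose members carry a latent depth in
      (0, 1) — shallow "gateway" regions versus deep local periphery;
    * a planted *core* of ``n_core`` nodes (21.5 % of nodes by default, the
      rich-club share of the upsampled brain network) at depth 0, densely
      interconnected among itself (``p_core``) and coupled to every
      community's shallow members (``p_core_periphery`` decaying with the
      partner's depth over ``gateway_scale``), so it is the junction through
      which communities communicate;
    * within-community connectivity decaying with depth difference
      (``depth_scale``) plus a local-cliquiness boost at depth
      (``clique_gain``), so deep regions are locally clustered but globally
      remote;
    * log-normal edge weights with large edgewise dispersion (``noise_sd``)
      standing in for right-skewed fiber counts, and mild node-level
      strength propensities (``strength_heterogeneity``);
    * a thin mesh of weak direct between-community edges (``p_inter``,
      ``w_inter``) that barely carries any shortest path but keeps lesioned
      networks connected.
    """

    n: int = 200
    n_core: int = 43  # round(0.215 * 200): the rich-club share of nodes
    communities: int = 4
    w_core: float = 25.0
    w_intra: float = 20.0
    w_inter: float = 2.0
    p_core: float = 0.9
    p_intra: float = 0.6
    p_inter: float = 0.05
    w_core_periphery: float = 20.0
    p_core_periphery: float = 0.5
    depth_scale: float = 0.4  # e-folding of within-community edge probability in depth
    gateway_scale: float = 0.2  # e-folding of core coupling with partner depth
    clique_gain: float = 2.0  # local edge-density boost for deep node pairs
    noise_sd: float = 1.0  # sigma of the log-normal edgewise weight noise
    strength_heterogeneity: float = 0.2  # sigma of peripheral node propensity
    core_heterogeneity: float = 0.2  # sigma of core node propensity
    coord_spread: float = 10.0  # sd (mm) of node scatter around its community center
    seed: int = 0

    def __post_init__(self):
        if not (self.w_core > self.w_intra > self.w_inter > 0):
            raise ValueError("need w_core > w_intra > w_inter > 0")
        for p in (self.p_core, self.p_intra, self.p_inter, self.p_core_periphery):
            if not 0 < p <= 1:
                raise ValueError("connection probabilities must be in (0, 1]")
        if not 0 < self.n_core < self.n:
            raise ValueError("core size must be in (0, n)")
        if not 1 <= self.communities <= self.n // 2:
            raise ValueError("community count must be in [1, n/2]")
        for s in (self.noise_sd, self.strength_heterogeneity, self.core_heterogeneity,
                  self.depth_scale, self.gateway_scale):
            if s < 0:
                raise ValueError("scales must be nonnegative")


DEFAULT_SPEC = SyntheticSpec()


def _lognormal_mean(rng: np.random.Generator, sigma: float, size: int):
    """Log-normal draws with arithmetic mean 1."""
    return rng.lognormal(-0.5 * sigma**2, sigma, size)


def make_modular_connectome(spec: SyntheticSpec = DEFAULT_SPEC):
    """Build (connectome, node table) with a planted connector core.

    Communities are contiguous index blocks named ``subcortical`` (the
    first) and ``lobe_1`` … ; core membership is spread evenly across
    communities and flagged ``rich_club``.  Edge presence is Bernoulli with
    the block- and depth-dependent probabilities described on
    :class:`SyntheticSpec`; the weight of a present edge is log-normal
    around the block mean scaled by both endpoints' propensities.  Isolated
    nodes are reattached to their community and residual components bridged
    at ``w_inter``, so the output always passes connectome validation.
    Anatomic coordinates are Gaussian clusters around random community
    centers, independent of the drawn edges, mirroring the dissociation
    between anatomic location and coupling pattern.
    """
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n, spec.communities
    community = (np.arange(n) * c) // n
    is_core = np.zeros(n, dtype=bool)
    is_core[np.unique((np.arange(spec.n_core) * n / spec.n_core).astype(int))] = True
    if is_core.sum() < spec.n_core:  # collisions from rounding: top up deterministically
        extra = np.setdiff1d(np.arange(n), np.flatnonzero(is_core))
        is_core[extra[: spec.n_core - is_core.sum()]] = True

    propensity = _lognormal_mean(rng, spec.strength_heterogeneity, n)
    propensity[is_core] = _lognormal_mean(rng, spec.core_heterogeneity, int(is_core.sum()))
    depth = np.where(is_core, 0.0, rng.random(n))

    iu, ju = np.triu_indices(n, k=1)
    both_core = is_core[iu] & is_core[ju]
    one_core = is_core[iu] ^ is_core[ju]
    same_comm = community[iu] == community[ju]
    ddiff = np.abs(depth[iu] - depth[ju])
    dperi = np.where(is_core[iu], depth[ju], depth[iu])  # peripheral partner's depth
    davg = 0.5 * (depth[iu] + depth[ju])

    p_within = np.minimum(
        spec.p_intra * np.exp(-ddiff / spec.depth_scale) * (1 + spec.clique_gain * davg),
        1.0,
    )
    p = np.where(both_core, spec.p_core,
                 np.where(one_core, spec.p_core_periphery * np.exp(-dperi / spec.gateway_scale),
                          np.where(same_comm, p_within, spec.p_inter)))
    mean = np.where(both_core, spec.w_core,
                    np.where(one_core, spec.w_core_periphery,
                             np.where(same_comm, spec.w_intra, spec.w_inter)))
    mean = mean * propensity[iu] * propensity[ju]
    present = rng.random(iu.size) < p
    weights = _lognormal_mean(rng, spec.noise_sd, iu.size) * mean * present

    w = np.zeros((n, n))
    w[iu, ju] = weights
    w[ju, iu] = weights

    # repair: reattach isolated nodes within their community, bridge components
    degree = (w > 0).sum(axis=1)
    for i in np.flatnonzero(degree == 0):
        peers = np.flatnonzero((community == community[i]) & (np.arange(n) != i))
        if peers.size == 0:
            peers = np.flatnonzero(np.arange(n) != i)
        j = int(rng.choice(peers))
        w[i, j] = w[j, i] = spec.w_inter
    ncomp, comp = connected_components((w > 0).astype(np.int8), directed=False)
    if ncomp > 1:
        main = int(np.argmax(np.bincount(comp)))
        main_nodes = np.flatnonzero(comp == main)
        for k in range(ncomp):
            if k == main:
                continue
            a = int(rng.choice(np.flatnonzero(comp == k)))
            b = int(rng.choice(main_nodes))
            w[a, b] = w[b, a] = spec.w_inter

    centers = rng.uniform(-60.0, 60.0, size=(c, 3))
    xyz = centers[community] + rng.normal(0.0, spec.coord_spread, size=(n, 3))

    width = max(3, len(str(n - 1)))
    labels = tuple(f"N{i:0{width}d}" for i in range(n))
    lobes = tuple("subcortical" if community[i] == 0 else f"lobe_{community[i]}"
                  for i in range(n))
    connectome = WeightedConnectome(w, labels)
    table = NodeTable(labels, lobes, xyz, is_core)
    return connectome, table


def make_swiss_roll(m: int, noise_sd: float = 0.0, seed: int = 0):
    """Sample the Swiss roll: ``(t·cos t, h, t·sin t)`` with t, h uniform.

    Returns ``(ambient, intrinsic)`` where ``intrinsic[:, 0]`` is the arc
    length along the spiral and ``intrinsic[:, 1]`` the height, so Euclidean
    distances between intrinsic rows are true distances on the unrolled
    manifold.  Gaussian noise of sd ``noise_sd`` perturbs the ambient
    coordinates only.
    """
    if m < 10:
        raise ValueError("need at least 10 points")
    rng = np.random.default_rng(seed)
    t = 1.5 * np.pi * (1.0 + 2.0 * rng.random(m))
    h = 21.0 * rng.random(m)
    ambient = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
    ambient = ambient + rng.normal(0.0, noise_sd, size=ambient.shape)
    arclen = 0.5 * (t * np.sqrt(1.0 + t * t) + np.arcsinh(t))
    intrinsic = np.column_stack([arclen, h])
    return ambient, intrinsic


def make_label_volume(shape, n_regions: int, seed: int = 0,
                      voxel_size=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Voronoi tessellation of a voxel grid around random seed voxels.

    Regions partition the whole grid (labels 1..n_regions); contiguity is
    not guaranteed and not required by the subdivision algorithm, which
    treats regions as point sets.
    """
    shape = tuple(int(s) for s in shape)
    if int(np.prod(shape)) < n_regions:
        raise ValueError("grid smaller than the requested number of regions")
    rng = np.random.default_rng(seed)
    flat = rng.choice(int(np.prod(shape)), size=n_regions, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, shape)).astype(float)
    grid = np.indices(shape).reshape(3, -1).T.astype(float)
    _, nearest = cKDTree(seeds).query(grid)
    labels = (nearest + 1).astype(np.int32).reshape(shape)
    return LabelVolume(labels, voxel_size)
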