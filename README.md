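# conngeo

**Intrinsic geometry of weighted brain connectomes.**

Structural connectomes are usually drawn in anatomic space, but the shape a
brain network *actually* has is determined by its coupling pattern, not by
where its regions sit in the skull. `conngeo` builds that intrinsic geometry:
it represents every node of a weighted network by its vector of graph
distances to all other nodes, embeds those vectors into two or three
dimensions with classical MDS or Isomap, validates the embedding against
nodal communication efficiency, and probes its stability with targeted and
random lesion simulations. A region-subdivision (atlas upsampling) algorithm
and a synthetic connectome generator round out the toolkit, so every analysis
runs end-to-end without any private imaging data.

The package is aimed at researchers working with structural connectivity
matrices (tractography fiber counts or any nonnegative coupling strengths)
who want a topology-faithful, low-dimensional picture of their network and
quantitative readouts of how that picture responds to node loss.

## The model

For a symmetric nonnegative coupling matrix `W` on `n` nodes:

1. **Edge lengths.** Each edge gets length `1 / W_ij` — strong coupling means
   short distance; zero coupling means no edge.
2. **Graph distances.** `GraphDistance_ij` is the shortest-path length
   between `i` and `j` (Dijkstra over the edge lengths). Disconnected inputs
   are rejected.
3. **High-dimensional representation.** Node `i` is placed at
   `d_i = (GraphDistance_i1, …, GraphDistance_in)` in `ℝⁿ`; two nodes are
   close iff they couple to the whole network in a similar way, i.e.
   `‖d_k − d_l‖ = sqrt(Σ_i (GraphDistance_ki − GraphDistance_li)²)` is small.
4. **Embedding.** Classical (Torgerson) MDS eigendecomposes the
   double-centered squared distance matrix `B = −½ J D⁽²⁾ J`; Isomap first
   replaces the ambient distances with geodesics along a k-nearest-neighbor
   graph (k grown automatically until the graph connects), then applies the
   same MDS. The top-`d` spectrum gives the coordinates; centroids sit at the
   origin.
5. **Validation.** A node's *nodal path length* (mean graph distance to all
   other nodes) is regressed on its Euclidean distance to the embedding
   center; a high `r²` means the space places efficient communicators
   centrally. A *dimension sweep* reports the residual RMSE of that
   regression for `d = 1…8`.
6. **Lesions.** Nodes are removed by targeted schemes (strength ↓,
   clustering ↑, nodal path length ↑, betweenness ↓, embeddedness ↓,
   rich-club or subcortical flags, custom rankings) or uniformly at random;
   survivors are re-embedded from scratch and scored with the cohesion
   statistic `d̄`, the mean distance of embedded nodes to the embedding
   center, plus a variant normalized by the surviving mean coupling weight.

## Worked example

```python
from dataclasses import replace
from conngeo import IntrinsicGeometry
from conngeo.synthetic import DEFAULT_SPEC, make_modular_connectome

connectome, nodes = make_modular_connectome(replace(DEFAULT_SPEC, seed=1))
model = IntrinsicGeometry(connectome, nodes)
result = model.fit(method="isomap", dim=3)
print(result.summary())
```

```
Intrinsic geometry fit
==========================================================
nodes:                 200
method:                isomap
target dimension:      3
neighborhood k used:   3
retained eigenvalues:  [48.96, 41.82, 29.71]
residual variance:     0.4353
cohesion d-bar:        0.6627
----------------------------------------------------------
distance-to-center ~ nodal path length (OLS)
  r^2:                 0.8661
  slope:               27.8460
  intercept:           -1.0523
```

The `r² = 0.87` says that in this Isomap space a node's distance to the
embedding center is almost a linear readout of its communication efficiency.
The same regression in the MDS space of this network gives `r² ≈ 0.26`, and
against the (deliberately decoupled) anatomic coordinates `r² ≈ 0.01` —
nonlinear reduction recovers structure the linear one blurs and anatomy
never had.

Ranking nodes by center distance puts the planted rich-club core at the
middle of the geometry:

```python
ranked = result.rank_table()
print(ranked.head(5).to_string(index=False))
```

```
label  distance  rich_club        lobe  rank
 N045  0.026036      False subcortical     0
 N046  0.040754       True subcortical     1
 N051  0.059199       True      lobe_1     2
 N018  0.099136       True subcortical     3
 N144  0.101470       True      lobe_2     4
```

with mean rank 31.3 for core nodes versus 118.2 for the periphery. Deleting
that core (21.5 % of nodes) and re-embedding inflates the cohesion statistic
from `d̄ = 0.663` to `0.994`, beyond the 95th percentile of 500 random
removals of the same size — the geometric signature of losing the network's
hub infrastructure:

```python
lesioned = model.lesion("rich_club", fraction=0.215)
print(lesioned.dbar_raw)          # 0.994
```

A command-line interface mirrors the library
(`conngeo embed|validate|lesion|subdivide|synth|pipeline`); see
`conngeo --help`.

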