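# bionet3d

Headless 3D visualization and analysis toolkit for biomolecular
networks: protein–protein interactomes, co-expression and metabolite
networks, gene–disease–drug graphs, residue-contact maps.  It computes
3D layouts, graph clusterings, bundled edge routings, and topology
statistics, and renders them to print-ready PNG snapshots and rotating
GIF movies — everything scriptable, seeded, and reproducible, with no
display required.

## What it computes

**Seven 3D layout engines.**  A graph G(V, E) is embedded in a bounded
volume by one of:

- `fr` — classic spring embedder with attractive force
  f_a(ij) = d²ᵢⱼ/k, repulsive force f_r(ij) = −k²/dᵢⱼ, and equilibrium
  length k = ∛(volume/n);
- `linlog` — the r-PolyLog energy
  U_r(p) = Σ_{uv∈E} (1/r)‖p(u)−p(v)‖^r − Σ_{pairs} w_u w_v ln‖p(u)−p(v)‖
  (node- or degree-weighted edge-repulsion variants; r=1 is the lin-log
  model that separates clusters by cut density, r=3 matches the spring
  embedder's equilibrium);
- `hybrid` — spectral bisection by the Laplacian's Fiedler vector
  (power iteration), then independent spring layouts per half;
- `coarse` — multilevel: heavy-edge matching coarsens the graph to ≤ 3
  nodes (or until a round shrinks it by less than rate 0.75), lays out
  the coarsest level, and prolongs with refinement;
- `anneal` — five-phase simulated-annealing schedule (liquid,
  expansion, cooldown, crunch, simmer) with edge cutting: a fraction
  (default 0.8) of the longest edges lose their attraction each step so
  clusters separate; 0 reproduces plain `fr` exactly;
- `semantic` — nodes binned onto equidistant z-levels (default 7) by
  descending degree or a user-supplied layer map (gene/disease/drug
  tiers), with a 2D spring pass in-plane;
- `hemisphere` — deterministic placement on an upper hemisphere,
  x = R·cos(lat)·cos(lon), y = R·sin(lon)·cos(lat), z = R·sin(lat),
  degree-ranked along an equal-area spiral with the top hub at the pole.

**Three clustering algorithms** with the modularity score
Q = Σ_c (e_c/m − (d_c/2m)²): edge-betweenness (Girvan–Newman) removal
sweep with a ⌈0.2·m⌉ removal budget, singleton protection, and the
best-Q snapshot; Markov clustering (expansion/inflation on the
column-stochastic flow matrix, sparse); and Newman's leading-eigenvector
method on the modularity matrix.  Cluster layouts place each cluster in
a translucent bubble (members on its hemisphere) or as pie-like slices
of one hemisphere (3D Circos).

**Force-directed edge bundling** with the four-factor compatibility
product (angle × scale × position × visibility): compatible edges above
a threshold (default 0.6) attract each other's subdivision points over
6 cycles, merging adjacent edges into wire-like highways.

**Topology statistics**: degree distribution, neighborhood
connectivity, local/average clustering coefficients, closeness (raw
reciprocal-sum, weights as lengths), node betweenness, diameter and
average shortest path, shortest-path load, shared nearest neighbors —
with nodes in components of ≤ 3 nodes excluded from the clustering
coefficient and closeness, as rank-ordered tables and distribution
plots.

## Worked example

A barbell network (two triangles joined by one bridge) through the
pipeline:

```sh
bionet3d fixtures --family barbell --n 6 --out-dir fx
bionet3d -v cluster fx/network.tsv --algo ebc --out-dir cl
# INFO ebc removed=2 best_Q=0.3571
# INFO cluster algo=ebc n=6 m=7 k=2 elapsed=0.00s
bionet3d layout fx/network.tsv --algo hemisphere --radius 5 --out-dir lo
bionet3d stats fx/network.tsv --out-dir st
bionet3d render fx/network.tsv lo/layout.tsv --out snap.png
```

The clustering removes the bridge first (its edge betweenness is 9 —
every one of the 3×3 cross-triangle shortest paths uses it) and reports
the two triangles at the best modularity Q = 0.357.  `clusters.tsv`
labels `a0..a2` as cluster 0 and `b0..b2` as cluster 1.  The layout
places the two degree-3 bridge endpoints first on the hemisphere —
`a2` exactly at the pole `(0, 0, 5)` — and `st/per_node.csv` ranks them
on top:

```
id,degree,neighborhood_connectivity,clustering_coefficient,closeness,betweenness,...
a2,3,2.333,0.333,0.1429,6.0,...
b0,3,2.333,0.333,0.1429,6.0,...
a0,2,2.5,1.0,0.1,0.0,...
```

with network summary n=6, m=7, diameter 3, average clustering
coefficient 0.778, network closeness 0.114, average shortest path 1.8.

## Layout of the package

| module | contents |
| --- | --- |
| `bionet3d.graph_core` | graph/edge/node model, TSV/CSV/SIF readers and writers, layout export |
| `bionet3d.layouts` | the seven layout engines and spectral bisection |
| `bionet3d.clustering` | Girvan–Newman, Markov clustering, leading eigenvector, modularity |
| `bionet3d.cluster_layouts` | bubble and 3D Circos cluster layouts, quotient graphs |
| `bionet3d.bundling` | 3D force-directed edge bundling |
| `bionet3d.netstats` | topology statistics, reports, distribution plots |
| `bionet3d.render` | camera/projection, PNG snapshots, rotation GIFs |
| `bionet3d.fixtures` | seeded synthetic-network generators |
| `bionet3d.cli` | `bionet3d` command-line interface |

See `docs/methods.md` for the models, parameter choices, and known
limitations.
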