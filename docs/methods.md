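# Methods

This note documents the models implemented in `bionet3d`, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the published models
leave the details open.

## Graph model and input conventions

Networks are undirected: the `directed` flag on an edge is a display
attribute (arrowheads) and never enters a layout, clustering, or
statistic.  Duplicate undirected edges in an input table are collapsed
with weights summed — the total interaction evidence is preserved —
and self-loops are rejected with a warning, since no downstream
computation consumes them.  Edge weight plays two roles, both
conventional in network biology: *length* in all shortest-path
quantities (closeness, betweenness, diameter; stronger = closer would
instead use the `weight_as_similarity` inversion), and *interaction
strength* in modularity and in the Markov flow matrix.  Mixed node
types (gene/drug/disease) are carried in the `texture` and color
columns rather than a dedicated type system.

## Force-directed layouts

The spring embedder uses f_a = d²/k and f_r = −k²/d with
k = ∛(volume/n); per-node displacement each iteration is the net force
direction capped by a temperature.  The published model specifies the
forces but no schedule, so the schedule is this package's: linear
temperature decay from one tenth of the cube side to zero over a
budget of `min(1000, max(50, 30·⌈10⁴/n⌉))` iterations.  The budget is
deliberately non-increasing in n — accuracy is traded for speed as
networks grow, keeping a 5,000-node layout near a minute on one core.
Coincident nodes (where the forces diverge) are separated once by a
10⁻⁴·k seeded jitter.  The returned configuration is the
lowest-stress one encountered (stress = Σ‖net force‖), which makes the
"final stress ≤ initial stress" contract hold unconditionally rather
than only when the trajectory happens to end well.

The r-PolyLog energy is minimized by gradient descent with step
halving on any energy increase, so accepted steps are monotone.  The
pair sum runs over unordered distinct pairs (the u=v term of a naive
V² sum is undefined).  In the edge-repulsion variant the log term is
weighted by deg(u)·deg(v); the printed source formula carries a
typesetting artifact around its minus sign, read here as plain
subtraction.  An isolated edge has closed-form equilibrium separation
d* = 1 for every r (d^r/r − ln d is minimized at 1), which the tests
use, and at r=3 that matches the spring-embedder length when k = 1.

Spectral bisection runs power iteration on σI − L with σ the
Gershgorin bound (twice the maximum weighted degree) and the constant
eigenvector deflated by projection each step, so the dominant
remaining direction is the Fiedler vector.  A sign split almost never
balances, so the split is at the median Fiedler value (ties toward
part A), guaranteeing |A| − |B| ≤ 1.  The solver's internal start
vector is fixed, making the routine deterministic.  When the Fiedler
eigenvalue is degenerate (cycles, cliques, stars), the eigen*vector*
is not unique and only the eigenvalue and balance are meaningful —
the test suite compares directions only when the spectral gap exceeds
10⁻⁶.  After bisection the halves are laid out independently and
offset along x with a gap of one part-diameter (the source describes
the partitioning but not the recombination).

Coarsening uses seeded randomized heavy-edge matching (the coarsening
rule is unspecified in the source; heavy-edge is the standard choice),
stopping at ≤ 3 nodes or when a round shrinks the graph by less than
the 0.75 rate.  Refinement at each finer level starts from the
parent's positions plus 0.05·k jitter and runs a quarter of the
adaptive budget at half temperature.

The annealed layout distributes its budget over five phases —
liquid 25%, expansion 25%, cooldown 25%, crunch 10%, simmer 15%, with
temperatures from 2k down to 0.05k — and cuts attraction on the
longest ⌈edge_cut·m·progress⌉ edges each iteration.  With edge_cut=0
the code path is the plain spring embedder with its own linear
schedule, so the two are bit-identical for the same seed.  The phase
proportions and temperature factors are this package's choices; the
phase names, the edge-cut semantics (0 = none, 1 = aggressive), and
the 0.8 default follow the published description.

## Semantic levels and hemispherical layouts

Semantic layout assigns each node to one of `n_layers` (default 7)
equidistant z-planes, spacing exactly `layer × spacing`.  A supplied
layer map is honored verbatim.  The automatic rule — the source says
only that nodes are assigned "consecutively" from topology — sorts
nodes by descending degree (ties by id) and cuts into contiguous
equal-size bins, moving any cut that falls inside a run of equal
degrees back to the run's start when that keeps every bin non-empty.
Consequences that the tests pin down: a star's hub occupies the top
layer alone, and a regular graph degrades to equal-size bins in id
order.  x, y come from a 2D spring pass over the whole graph followed
by an in-plane re-relaxation of each layer with 20% of the budget.

The hemispherical layout sorts nodes by descending degree and places
rank i at latitude arcsin(1 − (i+1)/n), longitude i × golden angle,
via x = R·cos(lat)·cos(lon), y = R·sin(lon)·cos(lat), z = R·sin(lat).
Rank 0 is pinned exactly at the pole (0, 0, R)+center.  "Equally
spaced" has no closed form for arbitrary n; the golden-angle spiral
with uniform z-steps gives near-equal area per node, and offsetting
the spiral one band below the pole keeps the minimum pairwise gap
within 30% of the √(2πR²/n) equal-area ideal across n (the pole would
otherwise pinch its nearest neighbor).

## Clustering

The edge-betweenness sweep recomputes betweenness after every removal,
never removes an edge that would isolate a node, and stops after
⌈0.2·m⌉ removals (both rules from the source); because the source
*also* describes stopping at optimized modularity, the sweep tracks Q
of the component partition after each removal and reports the best
snapshot — satisfying both statements.  Markov clustering iterates
expansion (matrix square), inflation (entrywise power 2.0 + column
renormalization), and pruning at 10⁻⁵ on a sparse column-stochastic
matrix with unit self-loops (standard regularization), reading
clusters as connected components of the converged flow's non-zero
structure.  The leading-eigenvector method recursively splits by the
sign of the top eigenvector of the group-restricted modularity matrix,
accepting a split only when ΔQ > 10⁻¹⁰.

A caution established while validating: on sparse planted partitions
(e.g. four 20-node communities at p_in=0.3, p_out=0.01), *exact*
recovery by any of these three methods is the exception, not the rule
— boundary nodes are genuinely ambiguous, and Markov clustering at
inflation 2.0 fragments 20-node communities.  python-igraph's
implementations of Girvan–Newman and leading-eigenvector score
identically on the same graphs (per-seed agreement to three decimals),
so this is a property of the algorithms, not of this implementation.
Adjusted-Rand scores in that regime are high (0.7–1.0) even when the
partition is not exact.

## Cluster layouts

Bubble layout positions clusters by a spring (or lin-log) layout of
the quotient graph — inter-cluster edge weight is the edge *count* by
default (`--sum-weights` switches to weight sums) — then places each
cluster's members on its own bubble hemisphere.  Bubble radius is
c·∛size with c set so the largest bubble spans ≤ 15% of the quotient
layout's extent; a final pass uniformly rescales center offsets until
no two bubbles overlap (5% margin).  The 3D Circos layout splits
longitude into one contiguous slice per cluster, width proportional to
cluster size.  The source wants the globally most connected node "at
the center" yet also per-slice placement; reconciliation here: the
global hub's cluster takes the first slice, and each slice's own
top-degree node sits nearest the pole within the slice.  Slice order
after the first is by decreasing size, ties by label.

## Edge bundling

Compatibility of two straight edges is the product of the angle
(|cos θ|), scale (2/(l_avg/l_min + l_max/l_avg)), position
(l_avg/(l_avg + midpoint distance)), and visibility factors, each in
[0, 1]; the visibility term reduces algebraically to
max(0, 1 − |1 − t₀ − t₁|/|t₁ − t₀|) in the projection parameters of
one edge's endpoints onto the other's line, which is what the
vectorized implementation computes.  Pairs above the 0.6 threshold
attract each other's corresponding subdivision points (antiparallel
partners are paired reversed); same-edge neighbors are coupled by a
spring of stiffness K/(l·segments), K = 0.1.  Six cycles double the
subdivision count (1→64 interior points) while the step (initially
0.04 × mean edge length) and iteration count (50) halve.  These
constants follow the published force-directed bundling scheme.  Above
2,000 edges each edge keeps only its 20 most compatible partners —
without this, the O(m²) pair interaction dominates run time.
Zero-length edges (coincident endpoints in the layout) have no
direction and are carried through as straight degenerate polylines.
When a layout declares a hemisphere constraint, interior points are
re-projected to the sphere after every update so bundles stay on the
surface.

## Topology statistics

The ">3 nodes" rule is read strictly: only nodes in components of ≥ 4
nodes enter the clustering-coefficient and closeness tables; excluded
nodes are blank, not zero.  Closeness is the raw reciprocal distance
sum within the node's own component (a `normalized` variant
multiplying by component size − 1 is available for cross-graph
comparison).  Betweenness uses fractional credit across tied shortest
paths; shortest-path load is the integer count of shortest paths
through a node (stress).  Diameter is the largest finite pairwise
distance, so disconnected pairs never contribute.  Above 1,500 nodes,
betweenness and load switch from exact to 200 sampled source pivots
(scaled estimates); every oracle comparison in the test suite runs in
the exact regime.  All tables are rank-ordered by a chosen metric;
distribution plots render headless at 150 dpi on white.

## Rendering

A painter's-algorithm renderer: look-at view transform, perspective or
orthographic projection, glyphs and edges drawn back-to-front by
depth.  Spheres are shaded 2D impostors (radial highlight), bubbles
translucent discs, labels flat 2D text with a 1-px halo — a deliberate
simplification of texture-mapped 3D labels.  High resolution is a
single large canvas (capped at 20,000 px/side) rather than tile
assembly.  Outputs are byte-deterministic for fixed inputs and library
versions.  Intersecting glyphs are a known painter's-algorithm
limitation: depth order is per-glyph, not per-pixel.  Render quality
(glyph tessellation, polyline segments) and layout iteration budgets
are non-increasing step functions of network size.

## Synthetic generators

The fixture families emulate the *shapes* of real biomolecular data:
planted-partition graphs for modular metabolite/expression networks,
preferential attachment for hub-dominated interactomes, layered graphs
for gene–disease–drug integration, and a noisy 3D helix with a
distance-decaying correlation matrix (edges = top-K correlated pairs)
for physically constrained residue-contact networks.  They do not
reproduce degree-correlation structure, weight distributions, or the
biological annotations of real datasets — so passing tests demonstrate
algorithmic correctness and scaling behavior, not biological fidelity
on any particular published network.  All generators are deterministic
per seed.

## Problem sizes

Default test and acceptance runs use: oracle sweeps at n ≤ 8 (exhaustive
path enumeration stays trivial), spectral checks at n ≤ 10 (dense
eigendecomposition oracle), recovery at 4×20 nodes × 10 seeds, and one
full-pipeline run at 5,000 nodes / ~10,000 edges — large enough to
exercise the sparse and sampled code paths, small enough to keep a full
suite run in minutes on one core.
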