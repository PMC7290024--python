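# Methods

## Model and assumptions

The method assumes that cells sampled from a differentiation process lie
near a tree-structured manifold in feature space: local Euclidean (or
cosine) distances are trustworthy, global ones are not, and the
intrinsic geometry is captured by paths through a neighborhood graph.
The embedding target is not the raw data but a graph-derived proximity
matrix; the embedding space is the Poincaré disk because hyperbolic
area grows exponentially with radius, so a two-dimensional disk can
host a branching hierarchy with low distortion where a Euclidean plane
cannot.

Pipeline: (1) symmetric kNN graph with Gaussian edge weights
`exp(−d²/2σ²)`; (2) Relative Forest Accessibility (RFA) proximities
`P = (I + L)^{-1}` with `L = D − A` (doubly stochastic, symmetric,
positive definite — every eigenvalue of `I + L` is at least 1); (3) a
hyperbolic softmax `Q` over disk distances fitted to the row-normalized
target by minimizing `Σ_i KL(P_i‖Q_i) + KL(Q_i‖P_i)` with Riemannian
SGD; (4) downstream operations that use only hyperbolic distances and
the disk's isometry group.

## Parameters

| name | default | meaning |
|---|---|---|
| `k` | 30 | neighbors per cell; sets the granularity of "local". Typical useful range 15–30; the synthetic-tree examples use 15 because 150-cell fixtures are small. |
| `sigma` | 1.0 | Gaussian kernel width, in units of the feature-space metric; 1–2 works across the fixtures. |
| `gamma` | 2.0 | softmax temperature, dimensionless; larger values scatter the embedding less aggressively. |
| `learning_rate` | 0.1 | RSGD step size; a 10-epoch burn-in at a tenth of the rate settles the near-origin initialization. |
| `max_epochs` | 2000 | hard cap; early stopping (relative improvement < 1e−5 sustained over 50 epochs) usually ends runs sooner on easy targets. |
| `batch_size` | 0 (full batch) | rows per stochastic step. Full batch is deterministic-monotone and is the default at the problem sizes this package targets; row batching trades monotonicity for throughput. |
| `n_pcs` | auto | matrices wider than 100 features are reduced to 100 principal components; narrower ones are z-scored per feature. |

## Design choices where the construction was open

- **Symmetrization.** The kNN edge set uses the union rule (edge if
  either endpoint selects the other): it preserves connectivity better
  than the intersection rule, which matters because the method requires
  a connected graph. Ties at equal distance break by ascending index,
  and a cell is never its own neighbor.
- **Greedy connectivity.** While components remain, the globally
  shortest inter-component edge (exact O(n²) search, same metric as the
  kNN search) is added and its two components merged.
- **Shortest-path mode.** Edge lengths are the raw metric distances,
  not the Gaussian similarities — path lengths should accumulate
  distances. For the loss target, distances are converted to
  similarities via `exp(−d)` per row before normalization. RFA is the
  default mode.
- **Target normalization.** RFA rows include a dominant diagonal term
  (self-accessibility). The diagonal is zeroed and rows renormalized so
  each row is a distribution over the other n−1 cells, matching the
  softmax `Q` whose denominator also excludes self-similarity.
- **Riemannian gradient and retraction.** The disk's conformal metric
  gives the standard inverse-metric rescaling `(1−‖y‖²)²/4` of the
  Euclidean gradient. The update uses an additive retraction with
  radial projection to norm `1 − 1e−5`; the exact exponential map is
  available behind a flag but makes no practical difference at these
  step sizes.
- **Initialization.** i.i.d. uniform in a radius-1e−3 disk around the
  origin, from the run's seed. Near-origin starts keep early gradients
  well conditioned; final layouts are insensitive to the seed up to
  isometry, and all outputs are bit-reproducible for a fixed seed.
- **Recentering.** The Möbius translation `τ(·, v)` carries the origin
  to `v`; to carry the root to the origin we apply `τ(·, −y_root)`
  (verified by `τ(−v, v) = 0`). An optional rigid rotation afterwards
  aligns a reference direction with angle 0.
- **Lineages.** The root is excluded from angular clustering (its angle
  at the origin is undefined) and labeled −1. Complete linkage on the
  circular distance `min(|Δθ|, 2π−|Δθ|)` prevents chaining across the
  angular gaps between branches; the linkage is configurable.
- **Root suggestion.** The cell with minimal total hyperbolic distance
  to all others is reported as a candidate root but never auto-applied:
  centrally placed cells are typically early but need not be the true
  origin of the process.
- **Quality scores.** From the co-ranking matrix of the two rank
  orderings we compute `Q_NX(K)` and its random-baseline adjustment
  `R_NX(K) = ((n−1)Q_NX(K) − K)/(n−1−K)`. The curve is split at
  `K* = argmax_K R_NX(K)` (smallest K on ties); `Q_local` is the mean
  of `R_NX` over `K ≤ K*`, `Q_global` the mean over `K ≥ K*`, both
  clipped into [0, 1]. A perfect embedding gives 1 at every K; random
  rank assignments give ≈ 0. Rank ties break by sample index in both
  spaces, and the raw `Q_NX`/`R_NX` curves are exposed so alternative
  summaries can be recomputed. High-dimensional reference distances are
  kNN-graph geodesics with k = 20.

## Synthetic data: what it emulates and what it does not

`generate_tree` builds trees of line segments in `R^p` (default p = 20,
branch length 10, 30 cells per branch, 5 branches → 150 cells,
isotropic noise sd 0.5 — roughly a 5% noise-to-geometry ratio, which is
what a well-preprocessed PC representation of a clean differentiation
experiment looks like). Branch directions are orthogonalized against
the parent so branches are geometrically separable; topologies:
`random` (binary-ish random attachment), `star` (branches radiate from
the root — the fixture where angular lineages are unambiguous) and
`balanced` (a balanced binary tree with well-defined generations).
`generate_toggle_switch` integrates two mutually repressing genes
(`dx/dt = a/(1+y^h) − x`, a = 2, h = 4, chosen so the symmetric state
(1,1) is unstable between two mirrored attractors) from a common
perturbed start, labeling each cell by its attained attractor.

These fixtures have exact piecewise-linear (or smooth planar) geometry,
no dropout, no library-size variation, no batch effects and modest n.
Passing tests therefore demonstrate that the algorithm recovers known
hierarchies under clean conditions; they do not certify performance on
real scRNA-seq noise structure, which additionally depends on upstream
preprocessing.

## Numerical choices

- `arcosh`/`artanh` arguments are clamped to their domains with 1e−15
  slack; coincident points get distance 0 and a zero distance-gradient.
- RFA is computed by a dense symmetric positive-definite solve of
  `(I+L)X = I`; intended scale is n up to a few thousand (the solve is
  O(n³) and the loss is O(n²) per epoch). Tests and examples use
  n ≤ 200.
- The loss treats `0·log 0` as 0; softmax rows are strictly positive
  off-diagonal, so both KL directions stay finite for RFA targets.
- Embedding coordinates are written with `repr` round-tripping and read
  back with exact float parsing, so a rerun under the same
  configuration is byte-identical.

## Known limitations

- O(n²) memory and O(n³) RFA solve: not meant for atlas-scale inputs
  without landmarking or approximate neighbors, which are out of scope.
- Angular lineage detection presumes lineages occupy disjoint angular
  sectors around the chosen root; for roots deep inside one branch, or
  nested subtrees sharing a sector, the assignment degrades (adjusted
  Rand ≈ 0.87–0.93 across star-tree draws rather than 1.0).
- Full-batch descent with a constant step is monotone in practice at
  the default rate, but monotonicity is not guaranteed for arbitrary
  targets or rates; row-batched SGD is explicitly non-monotone.
- The two-dimensional disk is hard-coded; a three-dimensional ball
  would follow the same construction but is not implemented.
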