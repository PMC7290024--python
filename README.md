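# poincaremaps

Hyperbolic embeddings of single-cell data on the Poincaré disk, for
biologists and computational scientists studying cell differentiation.
Developmental processes are tree-shaped — progenitors branch into
increasingly specialized fates — and trees do not fit into flat
two-dimensional pictures: Euclidean projections must distort either the
local neighborhoods or the global layout of the branches. Hyperbolic
space is a continuous analogue of a tree (available volume grows
exponentially with radius), so two hyperbolic dimensions suffice to
preserve both. A single disk embedding then supports visualization,
clustering, lineage detection and pseudotime inference.

## Method

Given cells `x_1..x_n ∈ R^p` (expression values or PC scores):

1. **Local connectivity.** Build a symmetric k-nearest-neighbor graph,
   greedily bridge disconnected components with their shortest linking
   edge, and weight edges with a Gaussian kernel
   `w(i,j) = exp(−‖x_i − x_j‖² / 2σ²)`.
2. **Global proximities.** Convert the graph Laplacian `L = D − A` into
   the Relative Forest Accessibility index `P = (I + L)^{-1}` — a
   symmetric, doubly stochastic matrix whose entry `p_ij` is the
   probability that a random spanning forest contains a tree rooted at
   `i` that also reaches `j`. All-pairs shortest-path geodesics are
   available as an alternative.
3. **Hyperbolic embedding.** Place each cell at `y_i` in the open unit
   disk with the metric
   `d_p(y_i, y_j) = arcosh(1 + 2‖y_i−y_j‖² / ((1−‖y_i‖²)(1−‖y_j‖²)))`,
   define softmax similarities
   `q_ij = exp(−d_p(y_i,y_j)/γ) / Σ_{k≠i} exp(−d_p(y_i,y_k)/γ)`,
   and minimize the symmetric Kullback–Leibler divergence
   `Σ_i KL(P_i‖Q_i) + KL(Q_i‖P_i)` by Riemannian stochastic gradient
   descent: the Euclidean gradient is rescaled by the inverse conformal
   metric `(1−‖y‖²)²/4` and a retraction projects each update back into
   the disk.
4. **Downstream.** A Möbius translation (an exact hyperbolic isometry)
   recenters the disk on a known root cell; pseudotime is hyperbolic
   distance from the root, lineages come from agglomerative clustering
   of the angular coordinate, and any pairwise-dissimilarity clusterer
   works directly on the hyperbolic distance matrix. Embedding quality
   is scored with the co-ranking criteria `Q_local`/`Q_global ∈ [0,1]`.

## Worked example

`examples/01_embed_branching_tree.py` generates 150 cells along a
5-branch differentiation tree in 20 dimensions and embeds them:

```
optimized 2000 epochs: loss 387.86 -> 2.40 (0.6% of initial)
Spearman(hyperbolic radius, true depth) = 0.899
```

The loss drops to under 1% of its starting value, and after recentering
the disk on the true root, each cell's hyperbolic radius tracks its true
developmental depth — progenitors near the origin, mature cells near the
boundary. `examples/02_pseudotime_and_lineages.py` adds pseudotime and
lineage recovery on a star-shaped tree:

```
Spearman(pseudotime, true depth) = 0.818
adjusted Rand index(lineages, true branches) = 0.918
```

and `examples/03_quality_vs_pca.py` shows the co-ranking comparison
against a flat projection of the same data:

```
Poincare disk:  Q_local=0.842  Q_global=0.849
2-D PCA:        Q_local=0.754  Q_global=0.801
```

The same pipeline is scriptable from the shell
(`examples/05_cli_pipeline.sh`):

```bash
poincaremaps simulate --kind tree --seed 1 --out-prefix tree
poincaremaps embed tree_matrix.csv --k 15 --sigma 2.0 --gamma 2.0 \
    --seed 1 --root-id cell_0 --n-lineages 5
poincaremaps quality tree_matrix.csv embedding.csv
```

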