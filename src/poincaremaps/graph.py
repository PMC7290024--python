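"""Connected, Gaussian-weighted k-nearest-neighbor graphs.

First stage of the pipeline: estimate the *local* geometry of the data
manifold.  Each cell is linked to its k nearest neighbors under a chosen
metric; the graph is made connected by greedily bridging components with
their shortest inter-component edge; edges are then weighted with a
Gaussian kernel ``w(i,j) = exp(-d(i,j)^2 / (2 sigma^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import pairwise_distances

VALID_METRICS = ("euclidean", "cosine")


@dataclass
class ExpressionMatrix:
    """n samples x p features, with identifiers.

    ``values`` may hold raw expression, log-counts or PC scores -- the
    pipeline is agnostic as long as the chosen metric is meaningful.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, p = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feature_{j}" for j in range(p)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedGraph:
    """Symmetric kNN graph over the samples.

    ``distances`` holds the metric distance of every edge (CSR, symmetric,
    zero diagonal); ``weights`` is filled by :func:`gaussian_weights` with
    the Gaussian similarities in (0, 1].
    """

    n_vertices: int
    distances: sp.csr_matrix
    k: int
    metric_name: str
    weights: sp.csr_matrix | None = None
    sigma: float | None = None

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered vertex pairs with an edge."""
        coo = sp.triu(self.distances, k=1).tocoo()
        edges = {(int(i), int(j)) for i, j in zip(coo.row, coo.col)}
        # zero-distance edges (duplicate points) are stored as explicit zeros
        coo_all = self.distances.tocoo()
        edges |= {
            (min(int(i), int(j)), max(int(i), int(j)))
            for i, j in zip(coo_all.row, coo_all.col)
            if i != j
        }
        return edges

    def n_components(self) -> int:
        ncomp, _ = connected_components(self.distances, directed=False)
        return int(ncomp)

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency (Gaussian weights); requires weights."""
        if self.weights is None:
            raise ValueError("graph has no weights; call gaussian_weights first")
        return self.weights.toarray()


def _pairwise(X: np.ndarray, metric: str) -> np.ndarray:
    if metric not in VALID_METRICS:
        raise ValueError(f"metric must be one of {VALID_METRICS}, got {metric!r}")
    D = pairwise_distances(X, metric=metric)
    # guard tiny negative values from floating-point cancellation
    np.maximum(D, 0.0, out=D)
    return D


def _edges_to_csr(n: int, pairs: set[tuple[int, int]], D: np.ndarray) -> sp.csr_matrix:
    """Symmetric CSR of metric distances for the given unordered pairs.

    Zero-distance edges (coincident points) are kept as explicit entries so
    the sparsity pattern is the edge set.
    """
    rows, cols, vals = [], [], []
    for i, j in sorted(pairs):
        d = float(D[i, j])
        rows += [i, j]
        cols += [j, i]
        vals += [d, d]
    # coincident points produce explicit zero entries; csgraph treats stored
    # zeros in sparse input as genuine zero-weight edges, so the pattern IS
    # the edge set -- never call eliminate_zeros on this matrix
    return sp.csr_matrix(
        (np.asarray(vals), (np.asarray(rows, int), np.asarray(cols, int))), shape=(n, n)
    )


def build_knn_graph(X: ExpressionMatrix, k: int = 30, metric: str = "euclidean") -> WeightedGraph:
    """Symmetric k-nearest-neighbor graph (edge-set stage, unweighted).

    An edge i~j is present iff i is among the k nearest neighbors of j *or*
    vice versa (union symmetrization).  Self-neighbors are excluded and
    distance ties are broken by ascending vertex index, so the result is
    deterministic.

    Parameters
    ----------
    X : ExpressionMatrix
    k : number of neighbors, ``1 <= k < n``
    metric : "euclidean" or "cosine"
    """
    n = X.n_samples
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got k={k}")
    D = _pairwise(X.values, metric)
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf  # exclude self
        # stable argsort: ties at equal distance resolve to the smaller index
        order = np.argsort(d, kind="stable")[:k]
        for j in order:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return WeightedGraph(
        n_vertices=n,
        distances=_edges_to_csr(n, pairs, D),
        k=k,
        metric_name=metric,
    )


def enforce_connectivity(G: WeightedGraph, X: ExpressionMatrix) -> WeightedGraph:
    """Greedily bridge disconnected components until the graph is connected.

    At each step the globally shortest edge between any two currently
    disconnected components is added and the two components merge; this
    repeats until a single component remains.  All original edges are kept.
    """
    n = G.n_vertices
    ncomp, labels = connected_components(G.distances, directed=False)
    if ncomp == 1:
        return G
    D = _pairwise(X.values, G.metric_name)
    pairs = G.edge_set()
    labels = labels.copy()
    while ncomp > 1:
        best = None  # (dist, i, j)
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] != labels[j]:
                    d = D[i, j]
                    if best is None or d < best[0]:
                        best = (d, i, j)
        _, i, j = best
        pairs.add((i, j))
        labels[labels == labels[j]] = labels[i]
        ncomp -= 1
    return replace(G, distances=_edges_to_csr(n, pairs, D))


def gaussian_weights(G: WeightedGraph, X: ExpressionMatrix, sigma: float = 1.0) -> WeightedGraph:
    """Weight every edge with the Gaussian kernel over metric distances.

    ``w(i,j) = exp(-d(i,j)^2 / (2 sigma^2))`` on edges, 0 elsewhere.  The
    same metric that built the graph is used, so coincident points get
    weight exactly 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    coo = G.distances.tocoo()
    w = np.exp(-(coo.data**2) / (2.0 * sigma**2))
    weights = sp.csr_matrix((w, (coo.row, coo.col)), shape=G.distances.shape)
    return replace(G, weights=weights, sigma=sigma)


def knn_graph(
    X: ExpressionMatrix,
    k: int = 30,
    sigma: float = 1.0,
    metric: str = "euclidean",
) -> WeightedGraph:
    """Convenience wrapper: build, connect, weight."""
    G = build_knn_graph(X, k=k, metric=metric)
    G = enforce_connectivity(G, X)
    return gaussian_weights(G, X, sigma=sigma)
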