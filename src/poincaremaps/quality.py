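"""Scale-independent embedding quality via the co-ranking framework.

An embedding is judged by how well it preserves neighborhood *ranks*
between the high-dimensional space (distances taken as kNN-graph
geodesics) and the low-dimensional space (hyperbolic distances for disk
embeddings, Euclidean otherwise).  From the co-ranking matrix we compute
the neighborhood-preservation curve

    Q_NX(K) = (1/(K n)) sum_{k<=K} sum_{l<=K} C[k, l]

and its random-baseline adjustment

    R_NX(K) = ((n-1) Q_NX(K) - K) / (n - 1 - K),   K = 1 .. n-2,

which is 0 in expectation for a random embedding and 1 for a perfect one.
The curve is split at the K* maximizing R_NX; Q_local averages R_NX on
the local side (K <= K*) and Q_global on the global side (K >= K*).
Both scores live in [0, 1] (negative averages are clipped at 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ExpressionMatrix, build_knn_graph, enforce_connectivity
from .proximity import shortest_path_distances


@dataclass
class QualityScores:
    q_local: float
    q_global: float
    k_geodesic: int = 20

    def as_tuple(self) -> tuple[float, float]:
        return (self.q_local, self.q_global)


def highdim_geodesics(X: ExpressionMatrix, k: int = 20, metric: str = "euclidean") -> np.ndarray:
    """Geodesic distances in the original space via a connected kNN graph.

    Shortest-path lengths over metric edge distances approximate distances
    along the data manifold; k defaults to 20.
    """
    G = build_knn_graph(X, k=k, metric=metric)
    G = enforce_connectivity(G, X)
    return shortest_path_distances(G).P


def _rank_matrix(D: np.ndarray) -> np.ndarray:
    """rho[i, j] = rank of j among i's neighbors (1 = nearest), ties by index.

    Diagonal entries are 0 and never enter the co-ranking counts.
    """
    n = D.shape[0]
    rho = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        order = np.argsort(d, kind="stable")[: n - 1]
        rho[i, order] = np.arange(1, n)
    return rho


def coranking_matrix(D_high: np.ndarray, D_low: np.ndarray) -> np.ndarray:
    """(n-1) x (n-1) contingency table of neighbor ranks in both spaces.

    C[k-1, l-1] counts ordered pairs (i, j), i != j, with rank k in the
    high-dimensional space and rank l in the low-dimensional one.
    """
    n = D_high.shape[0]
    if D_low.shape != (n, n):
        raise ValueError("distance matrices must have identical shape")
    rho_h = _rank_matrix(D_high)
    rho_l = _rank_matrix(D_low)
    off = ~np.eye(n, dtype=bool)
    C = np.zeros((n - 1, n - 1), dtype=np.int64)
    np.add.at(C, (rho_h[off] - 1, rho_l[off] - 1), 1)
    return C


def qnx_curve(C: np.ndarray) -> np.ndarray:
    """Q_NX(K) for K = 1..n-1 from the co-ranking matrix."""
    n = C.shape[0] + 1
    block = np.cumsum(np.cumsum(C, axis=0), axis=1)
    K = np.arange(1, n)
    return np.diag(block) / (K * n)


def rnx_curve(C: np.ndarray) -> np.ndarray:
    """Baseline-adjusted curve R_NX(K), K = 1..n-2."""
    n = C.shape[0] + 1
    qnx = qnx_curve(C)[: n - 2]
    K = np.arange(1, n - 1)
    return ((n - 1) * qnx - K) / (n - 1 - K)


def coranking_scores(D_high: np.ndarray, D_low: np.ndarray, k_geodesic: int = 20) -> QualityScores:
    """Scalar quality pair (Q_local, Q_global) of an embedding.

    Split point K* = argmax_K R_NX(K) (smallest K on ties); Q_local is the
    mean of R_NX over K <= K*, Q_global the mean over K >= K*.
    """
    n = D_high.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 samples to compute co-ranking scores, got {n}")
    C = coranking_matrix(D_high, D_low)
    rnx = rnx_curve(C)
    k_star = int(np.argmax(rnx))
    q_local = float(np.mean(rnx[: k_star + 1]))
    q_global = float(np.mean(rnx[k_star:]))
    return QualityScores(
        q_local=max(0.0, min(1.0, q_local)),
        q_global=max(0.0, min(1.0, q_global)),
        k_geodesic=k_geodesic,
    )
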