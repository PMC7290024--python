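"""Global proximities on the kNN graph.

Second stage: turn local connectivity into global structure.  The default
is the Relative Forest Accessibility (RFA) index

    P = (I + L)^{-1},    L = D - A  the graph Laplacian,

whose entry ``p_ij`` is the probability that a random spanning forest of
the graph contains a tree rooted at i that also includes j.  P is
symmetric, positive definite and doubly stochastic; compared to shortest
paths it up-weights nodes lying on many shortest paths, which is exactly
the signal that exposes roots of hierarchies.  All-pairs shortest-path
geodesics are available as an alternative mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

from .graph import WeightedGraph


@dataclass
class ProximityMatrix:
    """n x n global proximities.

    mode="rfa": doubly stochastic forest-accessibility probabilities.
    mode="shortest_path": symmetric geodesic distances, zero diagonal.
    """

    P: np.ndarray
    mode: str  # "rfa" | "shortest_path"


@dataclass
class TargetDistribution:
    """Row-stochastic target for the embedding loss.

    Each row i is a probability distribution over the other n-1 points;
    the diagonal is exactly zero.
    """

    Ptarget: np.ndarray
    mode: str


def graph_laplacian(G: WeightedGraph) -> np.ndarray:
    """Combinatorial Laplacian L = D - A of the Gaussian-weighted graph."""
    A = G.adjacency()
    L = np.diag(A.sum(axis=1)) - A
    return L


def rfa_matrix(L: np.ndarray) -> ProximityMatrix:
    """Relative Forest Accessibility index P = (I + L)^{-1}.

    I + L is symmetric positive definite (eigenvalues >= 1) for any valid
    Laplacian, so the solve cannot be singular; a failure signals a
    malformed input.
    """
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    M = np.eye(n) + L
    try:
        P = scipy.linalg.solve(M, np.eye(n), assume_a="pos")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("I + L is not positive definite; malformed Laplacian") from exc
    # symmetrize away solver round-off
    P = 0.5 * (P + P.T)
    return ProximityMatrix(P=P, mode="rfa")


def shortest_path_distances(G: WeightedGraph) -> ProximityMatrix:
    """All-pairs shortest-path geodesics over metric edge lengths.

    Path lengths accumulate the raw metric distances stored on the edges
    (not the Gaussian similarities), so the result behaves like a distance.
    """
    ncomp, _ = connected_components(G.distances, directed=False)
    if ncomp != 1:
        raise ValueError(
            f"graph has {ncomp} components; run enforce_connectivity first "
            "(disconnected pairs would be at infinite distance)"
        )
    D = shortest_path(G.distances, method="D", directed=False)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return ProximityMatrix(P=D, mode="shortest_path")


def target_distribution(P: ProximityMatrix) -> TargetDistribution:
    """Normalize proximities into the row-stochastic loss target.

    The diagonal is zeroed so a point is never its own neighbor.  RFA rows
    are renormalized to sum to one.  Shortest-path distances are first
    converted to similarities with exp(-d) and then row-normalized.
    """
    M = np.array(P.P, dtype=float, copy=True)
    if P.mode == "shortest_path":
        M = np.exp(-M)
    elif P.mode != "rfa":
        raise ValueError(f"unknown proximity mode {P.mode!r}")
    np.fill_diagonal(M, 0.0)
    rows = M.sum(axis=1)
    if np.any(rows <= 0):
        bad = int(np.argmin(rows))
        raise ValueError(f"row {bad} of the proximity matrix is all zero; degenerate input")
    return TargetDistribution(Ptarget=M / rows[:, None], mode=P.mode)
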