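"""Laplacian, RFA index, shortest-path geodesics, target normalization."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from poincaremaps import (
    ExpressionMatrix,
    ProximityMatrix,
    WeightedGraph,
    gaussian_weights,
    graph_laplacian,
    knn_graph,
    rfa_matrix,
    shortest_path_distances,
    target_distribution,
)


def graph_from_edges(n, edges, lengths=None):
    """Small helper: explicit graph with given edge metric lengths."""
    rows, cols, vals = [], [], []
    for (i, j), d in zip(edges, lengths or [1.0] * len(edges)):
        rows += [i, j]
        cols += [j, i]
        vals += [d, d]
    return WeightedGraph(
        n_vertices=n,
        distances=sp.csr_matrix((vals, (rows, cols)), shape=(n, n)),
        k=1,
        metric_name="euclidean",
    )


def weighted(n, edges, weights):
    G = graph_from_edges(n, edges)
    rows, cols, vals = [], [], []
    for (i, j), w in zip(edges, weights):
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    G.weights = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    G.sigma = 1.0
    return G


def test_laplacian_single_unit_edge():
    G = weighted(2, [(0, 1)], [1.0])
    assert np.array_equal(graph_laplacian(G), [[1.0, -1.0], [-1.0, 1.0]])


def test_laplacian_unit_triangle():
    G = weighted(3, [(0, 1), (1, 2), (0, 2)], [1.0, 1.0, 1.0])
    L = graph_laplacian(G)
    assert np.array_equal(np.diag(L), [2.0, 2.0, 2.0])
    off = L[~np.eye(3, dtype=bool)]
    assert np.all(off == -1.0)


def test_laplacian_rows_sum_to_zero(rng):
    X = ExpressionMatrix(rng.normal(size=(20, 3)))
    L = graph_laplacian(knn_graph(X, k=3))
    assert np.allclose(L @ np.ones(20), 0.0, atol=1e-12)
    assert np.array_equal(L, L.T)


def test_rfa_of_empty_graph_is_identity():
    P = rfa_matrix(np.zeros((3, 3)))
    assert np.allclose(P.P, np.eye(3))


def test_rfa_two_node_closed_form():
    # (I + [[1,-1],[-1,1]])^{-1} = [[2,-1],[-1,2]]^{-1} = 1/3 [[2,1],[1,2]]
    P = rfa_matrix(np.array([[1.0, -1.0], [-1.0, 1.0]]))
    assert np.allclose(P.P, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)


@pytest.mark.parametrize("n,k,seed", [(10, 2, 0), (50, 4, 1), (120, 6, 2)])
def test_rfa_doubly_stochastic_and_symmetric(n, k, seed):
    X = ExpressionMatrix(np.random.default_rng(seed).normal(size=(n, 3)))
    P = rfa_matrix(graph_laplacian(knn_graph(X, k=k))).P
    assert np.abs(P.sum(axis=0) - 1.0).max() < 1e-8
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-8
    assert np.abs(P - P.T).max() < 1e-10
    assert P.min() > 0  # strictly positive on connected graphs


def test_adding_an_edge_increases_its_rfa_entry(rng):
    for _ in range(5):
        n = 8
        X = ExpressionMatrix(rng.normal(size=(n, 2)))
        G = knn_graph(X, k=2)
        P0 = rfa_matrix(graph_laplacian(G)).P
        A = G.weights.toarray()
        # pick a currently-absent pair and connect it with weight 0.5
        free = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] == 0]
        if not free:
            continue
        i, j = free[0]
        A[i, j] = A[j, i] = 0.5
        L = np.diag(A.sum(axis=1)) - A
        P1 = rfa_matrix(L).P
        assert P1[i, j] > P0[i, j]


def _bruteforce_shortest_paths(n, edges, lengths):
    adj = {i: [] for i in range(n)}
    for (i, j), d in zip(edges, lengths):
        adj[i].append((j, d))
        adj[j].append((i, d))
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for src in range(n):
        # enumerate every simple path from src (exponential, fine for n <= 8)
        stack = [(src, 0.0, {src})]
        while stack:
            node, dist, seen = stack.pop()
            for nxt, d in adj[node]:
                if nxt in seen:
                    continue
                nd = dist + d
                if nd < D[src, nxt]:
                    D[src, nxt] = nd
                stack.append((nxt, nd, seen | {nxt}))
    return D


@pytest.mark.parametrize(
    "n, edges, lengths",
    [
        (3, [(0, 1), (1, 2)], [1.0, 2.0]),  # path: d(0,2)=3
        (3, [(0, 1), (1, 2), (0, 2)], [1.0, 1.0, 5.0]),  # long edge bypassed: 2
        (6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)],
         [1.0, 2.0, 1.5, 0.5, 3.0, 2.5, 0.25]),
    ],
)
def test_shortest_paths_match_exhaustive_enumeration(n, edges, lengths):
    G = graph_from_edges(n, edges, lengths)
    D = shortest_path_distances(G).P
    expected = _bruteforce_shortest_paths(n, edges, lengths)
    assert np.allclose(D, expected, atol=1e-12)
    assert np.all(np.diag(D) == 0)
    assert np.allclose(D, D.T)
    # triangle inequality
    for a, b, c in itertools.permutations(range(n), 3):
        assert D[a, c] <= D[a, b] + D[b, c] + 1e-12


def test_shortest_paths_reject_disconnected_graph():
    G = graph_from_edges(4, [(0, 1), (2, 3)])
    with pytest.raises(ValueError, match="component"):
        shortest_path_distances(G)


def test_target_from_two_node_rfa():
    # zero the diagonal of [[2/3,1/3],[1/3,2/3]] and renormalize by 1/3
    P = rfa_matrix(np.array([[1.0, -1.0], [-1.0, 1.0]]))
    T = target_distribution(P).Ptarget
    assert np.allclose(T, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)


def test_target_rows_are_probability_distributions(rng):
    X = ExpressionMatrix(rng.normal(size=(30, 3)))
    for mode_fn in (rfa_matrix, None):
        G = knn_graph(X, k=4)
        P = rfa_matrix(graph_laplacian(G)) if mode_fn else shortest_path_distances(G)
        T = target_distribution(P).Ptarget
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diag(T) == 0)
        assert np.all(T >= 0)


def test_target_idempotent_on_already_normalized_rows():
    M = np.array([[0.0, 0.3, 0.7], [0.5, 0.0, 0.5], [0.9, 0.1, 0.0]])
    T = target_distribution(ProximityMatrix(P=M, mode="rfa")).Ptarget
    assert np.allclose(T, M, atol=1e-15)


def test_target_rejects_all_zero_row():
    M = np.array([[0.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="degenerate"):
        target_distribution(ProximityMatrix(P=M, mode="rfa"))
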