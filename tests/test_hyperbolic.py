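"""Poincare distance, softmax similarities, symmetric KL loss, RSGD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poincaremaps import (
    FitConfig,
    embedding_loss,
    fit,
    generate_tree,
    pairwise_poincare_distances,
    poincare_distance,
    retract,
    riemannian_gradient,
    similarity_matrix,
    translate,
)
from poincaremaps.hyperbolic import _loss_and_grad
from poincaremaps.graph import ExpressionMatrix
from poincaremaps.pipeline import RunConfig, embed_matrix
from poincaremaps.proximity import graph_laplacian, rfa_matrix, target_distribution
from poincaremaps.graph import knn_graph

disk_points = st.tuples(
    st.floats(-0.95, 0.95), st.floats(-0.95, 0.95)
).map(np.array).filter(lambda y: np.linalg.norm(y) < 0.95)


def test_distance_identity_and_known_value():
    assert poincare_distance(np.zeros(2), np.zeros(2)) == 0.0
    # d(0, (0.5, 0)) = arcosh(1 + 2*0.25/0.75) = arcosh(5/3) = ln 3
    d = poincare_distance(np.zeros(2), np.array([0.5, 0.0]))
    assert d == pytest.approx(math.log(3.0), abs=1e-12)


def test_distance_from_origin_closed_form(rng):
    # d(0, y) = 2 artanh(||y||)
    for _ in range(50):
        y = rng.uniform(-0.7, 0.7, size=2)
        d = poincare_distance(np.zeros(2), y)
        assert d == pytest.approx(2.0 * np.arctanh(np.linalg.norm(y)), abs=1e-10)


def test_distance_cross_checked_against_translation_route(rng):
    # translate y_i to the origin isometrically, then use the closed form
    for _ in range(20):
        a = rng.uniform(-0.6, 0.6, size=2)
        b = rng.uniform(-0.6, 0.6, size=2)
        direct = poincare_distance(a, b)
        moved = translate(b, -a)
        assert direct == pytest.approx(2.0 * np.arctanh(np.linalg.norm(moved)), abs=1e-9)
    # the spec'd concrete pair
    d = poincare_distance(np.array([0.3, 0.0]), np.array([0.0, 0.3]))
    img = translate(np.array([0.0, 0.3]), -np.array([0.3, 0.0]))
    assert d == pytest.approx(2.0 * np.arctanh(np.linalg.norm(img)), abs=1e-10)


def test_points_outside_disk_rejected():
    with pytest.raises(ValueError, match="disk"):
        poincare_distance(np.array([1.0, 0.0]), np.zeros(2))
    with pytest.raises(ValueError, match="disk"):
        pairwise_poincare_distances(np.array([[0.0, 0.0], [0.8, 0.8]]))


def test_metric_axioms_on_random_triples(rng):
    pts = rng.uniform(-0.65, 0.65, size=(1000, 3, 2))
    for a, b, c in pts:
        dab = poincare_distance(a, b)
        dba = poincare_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-12)
        assert poincare_distance(a, b) + poincare_distance(b, c) >= poincare_distance(a, c) - 1e-10
    assert poincare_distance(pts[0, 0], pts[0, 0]) == 0.0


def test_pairwise_matches_scalar_distance(rng):
    Y = rng.uniform(-0.6, 0.6, size=(8, 2))
    D = pairwise_poincare_distances(Y)
    for i in range(8):
        for j in range(8):
            assert D[i, j] == pytest.approx(poincare_distance(Y[i], Y[j]), abs=1e-12)


def test_similarity_rows_sum_to_one_and_equidistant_uniform():
    # three points at equal radius, 120 degrees apart: all pairwise
    # hyperbolic distances equal by symmetry, so q_ij = 1/2 off-diagonal
    r = 0.4
    ang = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    Y = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    Q = similarity_matrix(Y, gamma=1.5)
    assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-12)
    off = Q[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 0.5, atol=1e-12)
    assert np.all(np.diag(Q) == 0)


def test_similarity_matches_longhand_softmax(rng):
    # scalar oracle: evaluate the softmax entry by entry with math.exp
    Y = np.array([[0.1, 0.2], [-0.3, 0.4], [0.5, -0.1]])
    gamma = 2.0
    Q = similarity_matrix(Y, gamma=gamma)
    for i in range(3):
        terms = {
            j: math.exp(-poincare_distance(Y[i], Y[j]) / gamma)
            for j in range(3)
            if j != i
        }
        Z = sum(terms.values())
        for j, t in terms.items():
            assert Q[i, j] == pytest.approx(t / Z, abs=1e-12)


def test_similarity_rejects_bad_gamma():
    with pytest.raises(ValueError, match="gamma"):
        similarity_matrix(np.zeros((3, 2)), gamma=0.0)


def test_loss_zero_iff_target_equals_softmax():
    Y = np.array([[0.2, 0.0], [-0.1, 0.3], [0.0, -0.25]])
    Q = similarity_matrix(Y, gamma=1.0)
    assert embedding_loss(Q, Y, gamma=1.0) == pytest.approx(0.0, abs=1e-12)
    P = np.array([[0.0, 0.9, 0.1], [0.5, 0.0, 0.5], [0.3, 0.7, 0.0]])
    assert embedding_loss(P, Y, gamma=1.0) > 0


def test_loss_matches_longhand_symmetric_kl():
    Y = np.array([[0.1, 0.2], [-0.3, 0.4], [0.5, -0.1]])
    gamma = 2.0
    P = np.array([[0.0, 0.25, 0.75], [0.6, 0.0, 0.4], [0.5, 0.5, 0.0]])
    Q = similarity_matrix(Y, gamma=gamma)
    expected = 0.0
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            expected += P[i, j] * math.log(P[i, j] / Q[i, j])
            expected += Q[i, j] * math.log(Q[i, j] / P[i, j])
    assert embedding_loss(P, Y, gamma=gamma) == pytest.approx(expected, rel=1e-12)


def test_riemannian_gradient_scaling():
    g = np.array([2.0, -4.0])
    assert np.allclose(riemannian_gradient(g, np.zeros(2)), g / 4.0)
    near = np.array([0.999999, 0.0])
    assert np.linalg.norm(riemannian_gradient(g, near)) < 1e-9
    # stacked form
    Y = np.array([[0.0, 0.0], [0.5, 0.0]])
    G = np.array([[1.0, 0.0], [1.0, 0.0]])
    R = riemannian_gradient(G, Y)
    assert R[0, 0] == pytest.approx(0.25)
    assert R[1, 0] == pytest.approx((1 - 0.25) ** 2 / 4.0)


def test_retract_identity_and_projection():
    y = np.array([0.3, -0.2])
    assert np.allclose(retract(y, np.zeros(2)), y)
    out = retract(np.zeros(2), np.array([2.0, 0.0]))
    assert np.allclose(out, [1.0 - 1e-5, 0.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(disk_points, st.tuples(st.floats(-5, 5), st.floats(-5, 5)))
def test_retract_always_lands_in_disk(y, update):
    out = retract(y, np.array(update))
    assert np.linalg.norm(out) <= 1.0 - 1e-5 + 1e-12


def test_full_loss_gradient_matches_central_differences(rng):
    n = 5
    Y = rng.uniform(-0.4, 0.4, size=(n, 2))
    P = rng.uniform(0.1, 1.0, size=(n, n))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    loss, grad = _loss_and_grad(P, Y, 2.0)
    eps = 1e-6
    num = np.zeros_like(Y)
    for i in range(n):
        for d in range(2):
            Yp, Ym = Y.copy(), Y.copy()
            Yp[i, d] += eps
            Ym[i, d] -= eps
            num[i, d] = (_loss_and_grad(P, Yp, 2.0)[0] - _loss_and_grad(P, Ym, 2.0)[0]) / (2 * eps)
    rel = np.abs(grad - num).max() / np.abs(num).max()
    assert rel < 1e-4
    assert loss == pytest.approx(embedding_loss(P, Y, 2.0), rel=1e-12)


def test_two_point_fit_separates_and_decreases():
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    emb = fit(P, FitConfig(gamma=1.0, max_epochs=200, seed=0))
    h = emb.loss_history
    assert h[-1] <= h[0]
    assert np.all(np.diff(h) <= 1e-12)  # full batch: non-increasing
    assert np.linalg.norm(emb.Y, axis=1).max() < 1.0


def test_fit_is_deterministic_given_seed():
    tree = generate_tree(n_branches=3, points_per_branch=10, seed=3)
    X = tree.to_expression_matrix()
    T = target_distribution(rfa_matrix(graph_laplacian(knn_graph(X, k=5, sigma=2.0))))
    a = fit(T, FitConfig(max_epochs=60, seed=7))
    b = fit(T, FitConfig(max_epochs=60, seed=7))
    assert a.loss_history == b.loss_history  # bit-identical
    assert np.array_equal(a.Y, b.Y)
    c = fit(T, FitConfig(max_epochs=60, seed=8))
    assert not np.array_equal(a.Y, c.Y)


def test_fit_converges_on_three_branch_tree():
    tree = generate_tree(n_branches=3, points_per_branch=15, noise_sd=0.5, seed=4)
    emb = embed_matrix(
        tree.to_expression_matrix(),
        RunConfig(k=10, sigma=2.0, gamma=2.0, seed=4),
    )
    h = emb.loss_history
    assert h[-1] < 0.10 * h[0]
    assert len(h) - 1 <= 2000


def test_minibatch_mode_also_converges():
    tree = generate_tree(n_branches=3, points_per_branch=10, noise_sd=0.5, seed=5)
    X = tree.to_expression_matrix()
    T = target_distribution(rfa_matrix(graph_laplacian(knn_graph(X, k=5, sigma=2.0))))
    emb = fit(T, FitConfig(gamma=2.0, max_epochs=600, batch_size=8, seed=5))
    assert emb.loss_history[-1] < 0.5 * emb.loss_history[0]
    assert np.linalg.norm(emb.Y, axis=1).max() <= 1.0 - 1e-5 + 1e-12


def test_exponential_map_option_runs_and_converges():
    P = np.array([[0.0, 0.7, 0.3], [0.5, 0.0, 0.5], [0.4, 0.6, 0.0]])
    emb = fit(P, FitConfig(gamma=1.0, max_epochs=300, seed=0, use_exp_map=True))
    assert emb.loss_history[-1] <= emb.loss_history[0]
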