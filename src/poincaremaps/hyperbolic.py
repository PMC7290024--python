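"""Poincare-disk geometry and Riemannian optimization of the embedding.

The embedding lives in the open unit disk B = {y in R^2 : ||y|| < 1} with
the hyperbolic distance

    d_p(y_i, y_j) = arcosh(1 + 2 ||y_i - y_j||^2 / ((1-||y_i||^2)(1-||y_j||^2))).

Distances are amplified towards the boundary, giving exponentially growing
room -- the continuous analogue of a tree.  The target proximities P are
matched by a hyperbolic softmax

    q_ij = exp(-d_p(y_i, y_j)/gamma) / sum_{k != i} exp(-d_p(y_i, y_k)/gamma)

by minimizing the symmetric Kullback-Leibler divergence

    L(P; Y) = sum_i KL(P_i || Q_i) + KL(Q_i || P_i)

with Riemannian stochastic gradient descent: the Euclidean gradient is
rescaled by the inverse of the disk's conformal metric, (1-||y||^2)^2/4,
and the update is mapped back to the disk by a retraction (or, optionally,
the exact exponential map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS_BOUNDARY = 1e-5  # points are kept at norm <= 1 - EPS_BOUNDARY
_CLAMP = 1e-15  # slack when clamping arcosh/artanh arguments to their domain


@dataclass
class FitConfig:
    """Hyperparameters of the embedding optimization.

    gamma : softmax temperature; controls the scattering of the embedding
        (larger gamma spreads points towards the boundary more slowly).
    learning_rate : RSGD step size eta.
    max_epochs : hard cap on epochs; convergence typically needs far fewer.
    batch_size : rows per stochastic step; 0 means full-batch updates.
    early_stop_tol : relative loss improvement below which, sustained over
        ``patience`` epochs, optimization stops.
    burn_in : number of initial epochs run at eta/10 to settle the
        near-origin initialization (0 disables).
    """

    gamma: float = 2.0
    learning_rate: float = 0.1
    max_epochs: int = 2000
    batch_size: int = 0
    early_stop_tol: float = 1e-5
    patience: int = 50
    burn_in: int = 10
    use_exp_map: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")


@dataclass
class PoincareEmbedding:
    """n points in the open unit disk plus optimization provenance."""

    Y: np.ndarray
    gamma: float
    loss_history: list[float] = field(default_factory=list)
    seed: int = 0
    root_index: int | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != 2:
            raise ValueError("embedding must be an (n, 2) array")
        norms = np.linalg.norm(self.Y, axis=1)
        if np.any(norms >= 1.0):
            raise ValueError("all embedding points must lie strictly inside the unit disk")

    @property
    def n_points(self) -> int:
        return self.Y.shape[0]

    def distance_matrix(self) -> np.ndarray:
        return pairwise_poincare_distances(self.Y)


def _check_in_disk(y: np.ndarray, name: str = "point") -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.linalg.norm(y, axis=-1).max() >= 1.0:
        raise ValueError(f"{name} lies outside the open unit disk")
    return y


def poincare_distance(y_i: np.ndarray, y_j: np.ndarray) -> float:
    """Hyperbolic distance between two points of the open unit disk."""
    y_i = _check_in_disk(y_i, "y_i")
    y_j = _check_in_disk(y_j, "y_j")
    diff = y_i - y_j
    num = float(diff @ diff)
    den = (1.0 - float(y_i @ y_i)) * (1.0 - float(y_j @ y_j))
    arg = 1.0 + 2.0 * num / den
    return float(np.arccosh(max(arg, 1.0 + _CLAMP) if arg < 1.0 else arg))


def pairwise_poincare_distances(Y: np.ndarray) -> np.ndarray:
    """Full n x n hyperbolic distance matrix (symmetric, zero diagonal)."""
    Y = _check_in_disk(Y, "embedding")
    sq = np.einsum("ij,ij->i", Y, Y)
    u = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(u, 0.0, out=u)
    alpha = 1.0 - sq
    z = 1.0 + 2.0 * u / (alpha[:, None] * alpha[None, :])
    np.maximum(z, 1.0, out=z)
    D = np.arccosh(z)
    np.fill_diagonal(D, 0.0)
    return D


def similarity_matrix(Y: np.ndarray | PoincareEmbedding, gamma: float = 2.0) -> np.ndarray:
    """Row-stochastic hyperbolic softmax Q of the embedding.

    q_ij = exp(-d_p(y_i,y_j)/gamma) normalized over k != i; the diagonal
    is zero (a point is not its own neighbor, mirroring the target).
    """
    if isinstance(Y, PoincareEmbedding):
        gamma = Y.gamma
        Y = Y.Y
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    D = pairwise_poincare_distances(Y)
    S = np.exp(-D / gamma)
    np.fill_diagonal(S, 0.0)
    return S / S.sum(axis=1, keepdims=True)


def embedding_loss(Ptarget, Y, gamma: float = 2.0) -> float:
    """Symmetric KL divergence between target rows P_i and softmax rows Q_i."""
    P = Ptarget.Ptarget if hasattr(Ptarget, "Ptarget") else np.asarray(Ptarget, float)
    if isinstance(Y, PoincareEmbedding):
        gamma = Y.gamma
        Y = Y.Y
    Q = similarity_matrix(Y, gamma)
    return _symmetric_kl(P, Q)


def _symmetric_kl(P: np.ndarray, Q: np.ndarray) -> float:
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    p = P[off]
    q = Q[off]
    # 0 * log 0 := 0; q is strictly positive off-diagonal by construction
    kl_pq = np.sum(np.where(p > 0, p * (np.log(np.maximum(p, 1e-300)) - np.log(q)), 0.0))
    kl_qp = np.sum(q * (np.log(q) - np.log(np.maximum(p, 1e-300))))
    return float(kl_pq + kl_qp)


def riemannian_gradient(euclidean_grad: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rescale a Euclidean gradient by the inverse disk metric.

    The Poincare disk's conformal metric is g_y = (2/(1-||y||^2))^2 I, so
    the Riemannian gradient is ((1-||y||^2)^2 / 4) * euclidean gradient.
    Supports a single point (2,) or a stack (n, 2).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(euclidean_grad, dtype=float)
    sq = np.sum(y * y, axis=-1, keepdims=True)
    return ((1.0 - sq) ** 2 / 4.0) * g


def retract(y: np.ndarray, update: np.ndarray) -> np.ndarray:
    """Additive retraction with projection back into the disk.

    y' = y + update; if ||y'|| exceeds 1 - 1e-5 it is radially rescaled to
    that norm, so the result is always a valid disk point.
    """
    y = np.asarray(y, dtype=float)
    out = y + np.asarray(update, dtype=float)
    norms = np.linalg.norm(out, axis=-1, keepdims=True)
    limit = 1.0 - EPS_BOUNDARY
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(norms > limit, limit / norms, 1.0)
    return out * scale


def exp_map(y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exact exponential map of the Poincare disk at y applied to tangent v."""
    from .disk_ops import translate  # local import avoids a cycle

    y = np.atleast_2d(np.asarray(y, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    sq = np.einsum("ij,ij->i", y, y)
    lam = 2.0 / (1.0 - sq)
    nv = np.linalg.norm(v, axis=1)
    out = y.copy()
    m = nv > 0
    if np.any(m):
        t = np.tanh(np.clip(lam[m] * nv[m] / 2.0, 0.0, 20.0))
        w = (t / nv[m])[:, None] * v[m]
        # Mobius addition y (+) w, via the translation carrying 0 to y
        out[m] = np.vstack([translate(wi, yi) for wi, yi in zip(w, y[m])])
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    limit = 1.0 - EPS_BOUNDARY
    out *= np.where(norms > limit, limit / norms, 1.0)
    return out if out.shape[0] > 1 else out[0]


def _loss_and_grad(P: np.ndarray, Y: np.ndarray, gamma: float):
    """Loss and full Euclidean gradient dL/dY of the symmetric KL loss.

    Derivation: with logits s_ij = -d_ij/gamma and row-softmax Q,
    dL_i/dq_ij = -p_ij/q_ij + log(q_ij/p_ij) + 1, the softmax Jacobian
    gives dL_i/ds_ij = q_ij (A_ij - <Q_i, A_i>); d_ij enters rows i and j,
    so the pair sensitivity is G_ij = -(dL_i/ds_ij + dL_j/ds_ji)/gamma.
    The distance gradient is
    dd_ij/dy_i = c_ij * (4/(a_i a_j)) [(y_i - y_j) + (u_ij/a_i) y_i]
    with u = ||y_i-y_j||^2, a = 1-||y||^2, c = 1/sqrt(z^2-1), z the
    arcosh argument.
    """
    n = Y.shape[0]
    sq = np.einsum("ij,ij->i", Y, Y)
    u = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    np.maximum(u, 0.0, out=u)
    alpha = 1.0 - sq
    ab = alpha[:, None] * alpha[None, :]
    z = 1.0 + 2.0 * u / ab
    np.maximum(z, 1.0, out=z)
    D = np.arccosh(z)
    np.fill_diagonal(D, 0.0)

    S = np.exp(-D / gamma)
    np.fill_diagonal(S, 0.0)
    Q = S / S.sum(axis=1, keepdims=True)

    off = ~np.eye(n, dtype=bool)
    logQ = np.zeros_like(Q)
    logQ[off] = np.log(Q[off])
    logP = np.log(np.maximum(P, 1e-300))
    loss = float(
        np.sum(np.where((P > 0) & off, P * (logP - logQ), 0.0))
        + np.sum(np.where(off, Q * (logQ - logP), 0.0))
    )

    # A_ij = dL_i/dq_ij
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(off, -np.where(Q > 0, P / np.maximum(Q, 1e-300), 0.0) + (logQ - logP) + 1.0, 0.0)
    row_dot = np.einsum("ij,ij->i", Q, A)
    dL_ds = Q * (A - row_dot[:, None])  # dL_i/ds_ij, zero diagonal
    G = -(dL_ds + dL_ds.T) / gamma  # total dL/dd_ij per ordered pair (i,j)

    # chain through the distance: dd_ij/dy_i
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 1.0 / np.sqrt(np.maximum(z * z - 1.0, 1e-30))
    c[z <= 1.0 + 1e-15] = 0.0  # coincident points: gradient defined as 0
    F = G * c * (4.0 / ab)
    np.fill_diagonal(F, 0.0)
    # sum_j F_ij [(y_i - y_j) + (u_ij / a_i) y_i]
    grad = F.sum(axis=1)[:, None] * Y - F @ Y
    grad += ((F * u).sum(axis=1) / alpha)[:, None] * Y
    return loss, grad


def _row_grad(P: np.ndarray, Y: np.ndarray, gamma: float, rows: np.ndarray) -> np.ndarray:
    """Stochastic gradient: d l_i / dy_i for i in ``rows`` only.

    l_i = KL(P_i||Q_i) + KL(Q_i||P_i) depends on y_i through the distances
    d_ij for all j; cross-row couplings are ignored, which is the standard
    SGD decomposition of the loss as a sum over rows.
    """
    n = Y.shape[0]
    Yb = Y[rows]
    sqb = np.einsum("ij,ij->i", Yb, Yb)
    sq = np.einsum("ij,ij->i", Y, Y)
    u = sqb[:, None] + sq[None, :] - 2.0 * (Yb @ Y.T)
    np.maximum(u, 0.0, out=u)
    ab = (1.0 - sqb)[:, None] * (1.0 - sq)[None, :]
    z = 1.0 + 2.0 * u / ab
    np.maximum(z, 1.0, out=z)
    D = np.arccosh(z)
    mask = np.ones_like(D, dtype=bool)
    mask[np.arange(len(rows)), rows] = False
    D[~mask] = 0.0

    S = np.exp(-D / gamma)
    S[~mask] = 0.0
    Q = S / S.sum(axis=1, keepdims=True)
    Pb = P[rows]
    logQ = np.zeros_like(Q)
    logQ[mask] = np.log(Q[mask])
    logP = np.log(np.maximum(Pb, 1e-300))
    A = np.where(mask, -np.where(Q > 0, Pb / np.maximum(Q, 1e-300), 0.0) + (logQ - logP) + 1.0, 0.0)
    row_dot = np.einsum("ij,ij->i", Q, A)
    dL_ds = Q * (A - row_dot[:, None])
    G = -dL_ds / gamma
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 1.0 / np.sqrt(np.maximum(z * z - 1.0, 1e-30))
    c[z <= 1.0 + 1e-15] = 0.0
    F = G * c * (4.0 / ab)
    F[~mask] = 0.0
    alpha_b = 1.0 - sqb
    grad = F.sum(axis=1)[:, None] * Yb - F @ Y
    grad += ((F * u).sum(axis=1) / alpha_b)[:, None] * Yb
    return grad


def fit(Ptarget, config: FitConfig | None = None, **kwargs) -> PoincareEmbedding:
    """Embed the target distribution into the Poincare disk by RSGD.

    Points start i.i.d. uniform in a disk of radius 1e-3 around the origin
    (near-origin starts keep early gradients well conditioned) and are
    updated per epoch, either full-batch (``batch_size=0``) or over
    shuffled row batches.  The run is deterministic given the seed.

    Raises a numerical-failure error naming the epoch and the first
    offending point if the loss or an update turns into NaN.
    """
    if config is None:
        config = FitConfig(**kwargs)
    P = Ptarget.Ptarget if hasattr(Ptarget, "Ptarget") else np.asarray(Ptarget, float)
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("target distribution must be square")
    rng = np.random.default_rng(config.seed)
    r = 1e-3 * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    Y = np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    step_fn = exp_map if config.use_exp_map else retract
    history: list[float] = []
    best = np.inf
    stalled = 0
    for epoch in range(config.max_epochs):
        eta = config.learning_rate / 10.0 if epoch < config.burn_in else config.learning_rate
        if config.batch_size and config.batch_size < n:
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                rows = order[start : start + config.batch_size]
                g = _row_grad(P, Y, config.gamma, rows)
                rg = riemannian_gradient(g, Y[rows])
                Y[rows] = step_fn(Y[rows], -eta * rg)
            loss, _ = _loss_and_grad(P, Y, config.gamma)
        else:
            loss, g = _loss_and_grad(P, Y, config.gamma)
            rg = riemannian_gradient(g, Y)
            Y = step_fn(Y, -eta * rg)
        if not np.isfinite(loss):
            bad = int(np.argmax(~np.isfinite(Y).all(axis=1))) if not np.isfinite(Y).all() else -1
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} (first offending point index {bad})"
            )
        history.append(loss)
        # early stopping on sustained lack of relative improvement
        if best - loss > config.early_stop_tol * max(abs(best), 1e-12):
            stalled = 0
        else:
            stalled += 1
            if stalled >= config.patience:
                break
        best = min(best, loss)
    # record the loss of the final iterate as well
    final_loss = embedding_loss(P, Y, config.gamma)
    history.append(final_loss)
    return PoincareEmbedding(Y=Y, gamma=config.gamma, loss_history=history, seed=config.seed)
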