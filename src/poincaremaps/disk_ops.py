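"""Operations on a fitted disk embedding.

The hyperbolic isometry group lets us re-center the embedding on a known
root cell without distorting any pairwise distance; pseudotime is then
simply hyperbolic distance from the root, and lineages fall out of
agglomerative clustering of the angular coordinate of the recentered
points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .hyperbolic import EPS_BOUNDARY, PoincareEmbedding, pairwise_poincare_distances


@dataclass
class PseudotimeVector:
    """Hyperbolic distance of every cell from the root cell."""

    values: np.ndarray
    root_index: int


@dataclass
class LineageAssignment:
    """Per-cell lineage labels from angular clustering.

    The root itself has an undefined angle at the origin and carries the
    sentinel label -1.
    """

    labels: np.ndarray
    n_lineages: int
    root_index: int


def translate(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Mobius translation of the disk carrying the origin to v.

    tau(x, v) = ((1 + 2<v,x> + ||x||^2) v + (1 - ||v||^2) x)
                / (1 + 2<v,x> + ||v||^2 ||x||^2)

    is a hyperbolic isometry: all pairwise d_p are preserved, tau(0,v)=v
    and tau(-v, v) = 0.  ``x`` may be a single point (2,) or a stack (n,2).
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if np.linalg.norm(v) >= 1.0 or np.linalg.norm(X, axis=1).max() >= 1.0:
        raise ValueError("translate requires all arguments strictly inside the unit disk")
    xx = np.einsum("ij,ij->i", X, X)
    vv = float(v @ v)
    vx = X @ v
    num = (1.0 + 2.0 * vx + xx)[:, None] * v[None, :] + (1.0 - vv) * X
    den = 1.0 + 2.0 * vx + vv * xx
    out = num / den[:, None]
    return out[0] if single else out


def recenter_to_root(
    Y: PoincareEmbedding, root_index: int, rotate: bool = False, reference_index: int | None = None
) -> PoincareEmbedding:
    """Isometrically move the root cell to the origin of the disk.

    Applies tau(., -y_root), the inverse of the translation carrying the
    origin to y_root, so the root maps exactly to 0 while every pairwise
    hyperbolic distance is preserved.  With ``rotate`` a subsequent rigid
    rotation (also an isometry) aligns the direction of a reference point
    (default: the point farthest from the new origin) with angle 0.
    """
    n = Y.n_points
    if not 0 <= root_index < n:
        raise IndexError(f"root_index {root_index} outside [0, {n})")
    out = translate(Y.Y, -Y.Y[root_index])
    out[root_index] = 0.0
    if rotate:
        norms = np.linalg.norm(out, axis=1)
        ref = int(np.argmax(norms)) if reference_index is None else int(reference_index)
        ang = np.arctan2(out[ref, 1], out[ref, 0])
        c, s = np.cos(ang), np.sin(ang)
        # rotate every row vector by -ang so the reference lands at angle 0
        out = out @ np.array([[c, -s], [s, c]])
    # translation can push near-boundary points marginally over the limit
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    limit = 1.0 - EPS_BOUNDARY
    scale = np.ones_like(norms)
    over = norms > limit
    scale[over] = limit / norms[over]
    out *= scale
    return replace(Y, Y=out, root_index=root_index)


def pseudotime(Y: PoincareEmbedding, root_index: int) -> PseudotimeVector:
    """Hyperbolic distance from the root: the Poincare pseudotime.

    Invariant under recentering since the translation is an isometry.
    """
    n = Y.n_points
    if not 0 <= root_index < n:
        raise IndexError(f"root_index {root_index} outside [0, {n})")
    root = Y.Y[root_index]
    sq = np.einsum("ij,ij->i", Y.Y, Y.Y)
    u = np.sum((Y.Y - root) ** 2, axis=1)
    z = 1.0 + 2.0 * u / ((1.0 - sq) * (1.0 - float(root @ root)))
    vals = np.arccosh(np.maximum(z, 1.0))
    vals[root_index] = 0.0
    return PseudotimeVector(values=vals, root_index=root_index)


def _circular_distance_matrix(theta: np.ndarray) -> np.ndarray:
    d = np.abs(theta[:, None] - theta[None, :])
    return np.minimum(d, 2.0 * np.pi - d)


def detect_lineages(
    Y: PoincareEmbedding, root_index: int, n_lineages: int, linkage: str = "complete"
) -> LineageAssignment:
    """Partition cells into lineages by angle around the recentered root.

    The embedding is recentered internally so the root sits at the origin;
    the remaining cells are clustered agglomeratively (complete linkage by
    default, to stop chains bridging the angular gap between branches) on
    the circular angular distance min(|t_i - t_j|, 2 pi - |t_i - t_j|).
    The root is excluded (label -1).
    """
    n = Y.n_points
    if n_lineages < 2:
        raise ValueError(f"n_lineages must be >= 2, got {n_lineages}")
    if n_lineages > n - 1:
        raise ValueError(f"n_lineages={n_lineages} exceeds the {n - 1} non-root cells")
    centered = recenter_to_root(Y, root_index)
    others = np.delete(np.arange(n), root_index)
    theta = np.arctan2(centered.Y[others, 1], centered.Y[others, 0]) % (2.0 * np.pi)
    D = _circular_distance_matrix(theta)
    model = AgglomerativeClustering(
        n_clusters=n_lineages, metric="precomputed", linkage=linkage
    )
    sub = model.fit_predict(D)
    labels = np.full(n, -1, dtype=int)
    labels[others] = sub
    return LineageAssignment(labels=labels, n_lineages=n_lineages, root_index=root_index)


def _kmedoids(D: np.ndarray, n_clusters: int, seed: int = 0, max_iter: int = 300) -> np.ndarray:
    """Seeded PAM-style k-medoids on a precomputed dissimilarity matrix."""
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    medoids = rng.choice(n, size=n_clusters, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(n_clusters):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new[c] = members[np.argmin(costs)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def cluster_embedding(
    Y: PoincareEmbedding,
    n_clusters: int,
    linkage: str = "average",
    method: str = "agglomerative",
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells on the full pairwise hyperbolic distance matrix.

    Any technique needing only pairwise dissimilarities applies on the
    disk; agglomerative clustering (default, average linkage) and a
    k-medoids alternative are provided.
    """
    n = Y.n_points
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    D = pairwise_poincare_distances(Y.Y)
    if method == "kmedoids":
        return _kmedoids(D, n_clusters, seed=seed)
    if method != "agglomerative":
        raise ValueError("method must be 'agglomerative' or 'kmedoids'")
    allowed = ("average", "complete", "single")
    if linkage not in allowed:
        raise ValueError(f"linkage must be one of {allowed}, got {linkage!r}")
    if n_clusters == n:
        return np.arange(n)
    model = AgglomerativeClustering(n_clusters=n_clusters, metric="precomputed", linkage=linkage)
    return model.fit_predict(D)


def suggest_root(Y: PoincareEmbedding) -> int:
    """Index of the cell with minimal total hyperbolic distance to all others.

    Cells close to many others sit near the origin and often come from an
    early developmental stage -- but they need not be the true root, so
    this is only a suggestion, never applied automatically.
    """
    D = pairwise_poincare_distances(Y.Y)
    return int(np.argmin(D.sum(axis=1)))
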