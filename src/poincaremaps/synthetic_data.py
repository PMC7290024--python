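"""Synthetic branching trajectories with known ground truth.

Real differentiation data arrive without labels; to test every stage of
the pipeline we generate (a) random branching trees of line segments in
feature space -- each branch leaves its parent's endpoint in a direction
orthogonalized against the parent's, so branches are geometrically
separable -- and (b) a two-gene toggle-switch: two mutually repressing
genes integrated from a common progenitor state, bifurcating into two
stable expression attractors, the simplest possible lineage decision.
Branch membership, depth from the root and the branch tree are returned
alongside the matrix, and every draw is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .graph import ExpressionMatrix


@dataclass
class SyntheticTrajectory:
    """Generated cells plus the ground truth that produced them."""

    X: np.ndarray
    branch_labels: np.ndarray
    depth: np.ndarray
    tree: dict[int, int]  # branch id -> parent branch id (-1 for the root branch)
    seed: int
    root_index: int = 0
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = [f"cell_{i}" for i in range(self.X.shape[0])]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    def to_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(values=self.X, sample_ids=list(self.sample_ids))


def _orthogonalized_direction(rng: np.random.Generator, parent_dir: np.ndarray | None, p: int) -> np.ndarray:
    d = rng.normal(size=p)
    if parent_dir is not None:
        d -= (d @ parent_dir) * parent_dir
    norm = np.linalg.norm(d)
    if norm < 1e-12:  # pragma: no cover - probability zero
        return _orthogonalized_direction(rng, parent_dir, p)
    return d / norm


def generate_tree(
    n_branches: int = 5,
    branch_length: float = 10.0,
    points_per_branch: int = 30,
    p: int = 20,
    noise_sd: float = 0.5,
    seed: int = 0,
    topology: str = "random",
) -> SyntheticTrajectory:
    """Branching tree of line segments in R^p.

    Branch 0 starts at the origin and contains the root cell (depth 0,
    index 0).  Topologies:

    - "random": every further branch attaches to a parent chosen
      uniformly among branches with fewer than two children (a
      "binary-ish" tree) and extends from the parent's endpoint in a
      random direction orthogonalized against the parent's direction;
    - "star": all branches radiate from the root itself in mutually
      orthogonalized directions -- the well-separated fixture where each
      branch occupies its own angular sector around the root;
    - "balanced": a balanced binary tree (branch b attaches to branch
      (b-1)//2), so generations of equal depth are well defined.

    Cells are placed uniformly along their branch segment and perturbed
    with isotropic Gaussian noise of standard deviation ``noise_sd``.
    ``depth`` is the exact arc length from the root to each cell's
    noiseless position; total cells = n_branches * points_per_branch.
    """
    if n_branches < 1:
        raise ValueError(f"n_branches must be >= 1, got {n_branches}")
    if p < 2:
        raise ValueError(f"p must be >= 2, got {p}")
    if points_per_branch < 1:
        raise ValueError(f"points_per_branch must be >= 1, got {points_per_branch}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if topology not in ("random", "star", "balanced"):
        raise ValueError(f"topology must be random, star or balanced, got {topology!r}")
    rng = np.random.default_rng(seed)

    tree: dict[int, int] = {0: -1}
    starts = {0: np.zeros(p)}
    dirs = {0: _orthogonalized_direction(rng, None, p)}
    base_depth = {0: 0.0}
    children = {0: 0}
    for b in range(1, n_branches):
        if topology == "star":
            parent = -1  # attaches at the root cell itself
            starts[b] = np.zeros(p)
            # orthogonalize against all previous star directions (as far
            # as p allows) so angular sectors are well separated
            d = rng.normal(size=p)
            for c in range(min(b, p - 1) + 1):
                prev = dirs[c] if c < b else None
                if prev is not None:
                    d -= (d @ prev) * prev
            nrm = np.linalg.norm(d)
            dirs[b] = d / nrm if nrm > 1e-12 else _orthogonalized_direction(rng, None, p)
            base_depth[b] = 0.0
            tree[b] = parent
            continue
        if topology == "balanced":
            parent = (b - 1) // 2
        else:
            candidates = [c for c in range(b) if children[c] < 2]
            parent = int(rng.choice(candidates))
        children[parent] = children.get(parent, 0) + 1
        children[b] = 0
        tree[b] = parent
        starts[b] = starts[parent] + branch_length * dirs[parent]
        dirs[b] = _orthogonalized_direction(rng, dirs[parent], p)
        base_depth[b] = base_depth[parent] + branch_length

    X_rows, labels, depths = [], [], []
    for b in range(n_branches):
        t = rng.uniform(0.0, branch_length, size=points_per_branch)
        t = np.sort(t)
        if b == 0:
            t[0] = 0.0  # the root cell sits exactly at the origin
        pts = starts[b][None, :] + t[:, None] * dirs[b][None, :]
        X_rows.append(pts)
        labels.append(np.full(points_per_branch, b))
        depths.append(base_depth[b] + t)
    X = np.vstack(X_rows)
    X = X + rng.normal(scale=noise_sd, size=X.shape) if noise_sd > 0 else X
    return SyntheticTrajectory(
        X=X,
        branch_labels=np.concatenate(labels),
        depth=np.concatenate(depths),
        tree=tree,
        seed=seed,
        root_index=0,
    )


def _toggle_rhs(_t, state, a, h):
    x, y = state
    return [a / (1.0 + y**h) - x, a / (1.0 + x**h) - y]


def generate_toggle_switch(
    n_cells: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
    a: float = 2.0,
    h: float = 4.0,
    t_max: float = 10.0,
) -> SyntheticTrajectory:
    """Two-gene toggle switch: a single bifurcation into two attractors.

    dx/dt = a/(1 + y^h) - x,  dy/dt = a/(1 + x^h) - y.  With a=2, h=4 the
    symmetric state x = y = 1 is an unstable fixed point and two mirrored
    stable attractors exist (one gene high, the other repressed).  Each
    cell starts near the symmetric progenitor state with a small random
    perturbation, is integrated for a random time in (0, t_max], and is
    reported with measurement noise.  Branch label 0/1 records which
    attractor the cell's (noiseless) trajectory converges to; depth is the
    integration time, and the first cell (t = 0) is the root.
    """
    if n_cells < 10:
        raise ValueError(f"n_cells must be >= 10, got {n_cells}")
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, t_max, size=n_cells))
    times[0] = 0.0
    X = np.zeros((n_cells, 2))
    labels = np.zeros(n_cells, dtype=int)
    for i, t_i in enumerate(times):
        start = np.array([1.0, 1.0]) + rng.normal(scale=0.05, size=2)
        if t_i > 0:
            sol = solve_ivp(
                _toggle_rhs, (0.0, t_i), start, args=(a, h), rtol=1e-8, atol=1e-10
            )
            X[i] = sol.y[:, -1]
            end = solve_ivp(
                _toggle_rhs, (t_i, max(t_max, 50.0)), X[i], args=(a, h), rtol=1e-8, atol=1e-10
            ).y[:, -1]
        else:
            X[i] = start
            end = solve_ivp(
                _toggle_rhs, (0.0, max(t_max, 50.0)), start, args=(a, h), rtol=1e-8, atol=1e-10
            ).y[:, -1]
        labels[i] = int(end[0] < end[1])
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    return SyntheticTrajectory(
        X=X,
        branch_labels=labels,
        depth=times,
        tree={0: -1, 1: 0},
        seed=seed,
        root_index=0,
    )
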