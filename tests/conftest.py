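import numpy as np
import pytest

from poincaremaps import generate_tree
from poincaremaps.pipeline import RunConfig, embed_matrix

# shared hyperparameters for the synthetic-tree fits: mid-range values from
# the method's typical ranges (k in 15-30, sigma in 1-2, gamma in 1-2)
TREE_PARAMS = dict(k=15, sigma=2.0, gamma=2.0)


@pytest.fixture(scope="session")
def default_tree():
    """Standard fixture: 5-branch random tree, n=150, moderate noise."""
    return generate_tree(seed=1)


@pytest.fixture(scope="session")
def default_tree_fit(default_tree):
    emb = embed_matrix(
        default_tree.to_expression_matrix(), RunConfig(seed=1, **TREE_PARAMS)
    )
    return default_tree, emb


@pytest.fixture(scope="session")
def star_tree_fit():
    """Noiseless star tree: branches radiate from the root, one angular
    sector each -- the well-separated lineage fixture."""
    traj = generate_tree(n_branches=5, points_per_branch=30, noise_sd=0.0,
                         seed=1, topology="star")
    emb = embed_matrix(traj.to_expression_matrix(), RunConfig(seed=1, **TREE_PARAMS))
    return traj, emb


@pytest.fixture(scope="session")
def balanced_tree_fit():
    """Noiseless balanced binary tree with three well-defined generations."""
    traj = generate_tree(n_branches=7, points_per_branch=20, noise_sd=0.0,
                         seed=2, topology="balanced")
    emb = embed_matrix(traj.to_expression_matrix(), RunConfig(seed=2, **TREE_PARAMS))
    return traj, emb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
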