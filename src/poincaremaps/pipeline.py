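"""End-to-end pipeline: matrix in, embedding (and downstream tables) out.

Stages: preprocess -> kNN graph -> global proximities -> hyperbolic fit
-> optional recentering / pseudotime / lineages.  Every stage logs its
key invariant (graph connected, target doubly stochastic, final loss) and
every parameter that affected the run lands in the JSON manifest, so a
rerun with the same configuration reproduces the embedding byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as pio
from .disk_ops import detect_lineages, pseudotime, recenter_to_root
from .graph import ExpressionMatrix, knn_graph
from .hyperbolic import FitConfig, PoincareEmbedding, fit
from .proximity import (
    graph_laplacian,
    rfa_matrix,
    shortest_path_distances,
    target_distribution,
)

logger = logging.getLogger("poincaremaps")


@dataclass
class RunConfig:
    """Everything that influences a pipeline run."""

    input_path: str | Path | None = None
    output_dir: str | Path = "."
    k: int = 30
    sigma: float = 1.0
    gamma: float = 2.0
    metric: str = "euclidean"
    mode: str = "rfa"  # or "shortest_path"
    learning_rate: float = 0.1
    max_epochs: int = 2000
    batch_size: int = 0
    seed: int = 0
    root_id: str | None = None
    n_lineages: int | None = None
    n_pcs: int | None = None
    log_level: str = "INFO"

    def validate(self, n: int | None = None) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if n is not None and self.k >= n:
            raise ValueError(f"k={self.k} must be < n={n}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError(f"metric must be euclidean or cosine, got {self.metric!r}")
        if self.mode not in ("rfa", "shortest_path"):
            raise ValueError(f"mode must be rfa or shortest_path, got {self.mode!r}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.n_lineages is not None and self.n_lineages < 2:
            raise ValueError(f"n_lineages must be >= 2, got {self.n_lineages}")


def embed_matrix(X: ExpressionMatrix, config: RunConfig) -> PoincareEmbedding:
    """Run preprocess -> graph -> proximities -> fit on an in-memory matrix."""
    config.validate(n=X.n_samples)
    t0 = time.perf_counter()
    Xp = pio.preprocess(X, n_pcs=config.n_pcs)
    logger.info("preprocess: %d x %d -> %d x %d (%.2fs)", X.n_samples, X.n_features,
                Xp.n_samples, Xp.n_features, time.perf_counter() - t0)

    t0 = time.perf_counter()
    G = knn_graph(Xp, k=config.k, sigma=config.sigma, metric=config.metric)
    assert G.n_components() == 1, "graph must be connected after enforce_connectivity"
    logger.info("graph: k=%d sigma=%.3g, connected, %d edges (%.2fs)",
                config.k, config.sigma, len(G.edge_set()), time.perf_counter() - t0)

    t0 = time.perf_counter()
    if config.mode == "rfa":
        P = rfa_matrix(graph_laplacian(G))
        dev = max(
            np.abs(P.P.sum(axis=0) - 1.0).max(), np.abs(P.P.sum(axis=1) - 1.0).max()
        )
        logger.info("proximity: RFA, doubly-stochastic deviation %.2e (%.2fs)",
                    dev, time.perf_counter() - t0)
    else:
        P = shortest_path_distances(G)
        logger.info("proximity: shortest paths (%.2fs)", time.perf_counter() - t0)
    target = target_distribution(P)

    t0 = time.perf_counter()
    emb = fit(
        target,
        FitConfig(
            gamma=config.gamma,
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            batch_size=config.batch_size,
            seed=config.seed,
        ),
    )
    logger.info("fit: %d epochs, loss %.4f -> %.4f (%.2fs)",
                len(emb.loss_history) - 1, emb.loss_history[0], emb.loss_history[-1],
                time.perf_counter() - t0)
    return emb


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Full pipeline from a matrix file to artifacts on disk.

    Writes ``embedding.csv`` and ``manifest.json``; with ``root_id`` also
    ``pseudotime.csv`` (and ``lineages.csv`` when ``n_lineages`` is set).
    Any stage failure aborts with a stage-labeled error and removes
    partial outputs.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    X = pio.load_matrix(config.input_path)
    config.validate(n=X.n_samples)

    root_index: int | None = None
    if config.root_id is not None:
        if config.root_id not in X.sample_ids:
            raise ValueError(f"root_id {config.root_id!r} is not among the sample ids")
        root_index = X.sample_ids.index(config.root_id)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        emb = embed_matrix(X, config)
        emb.root_index = root_index

        path = outdir / "embedding.csv"
        pio.write_embedding(path, emb, X.sample_ids)
        written["embedding"] = path

        if root_index is not None:
            pt = pseudotime(emb, root_index)
            path = outdir / "pseudotime.csv"
            pio.write_vector(path, pt.values, X.sample_ids, "pseudotime")
            written["pseudotime"] = path
            if config.n_lineages is not None:
                lin = detect_lineages(emb, root_index, config.n_lineages)
                path = outdir / "lineages.csv"
                pio.write_vector(path, lin.labels, X.sample_ids, "lineage")
                written["lineages"] = path
            centered = recenter_to_root(emb, root_index)
            path = outdir / "embedding_recentered.csv"
            pio.write_embedding(path, centered, X.sample_ids)
            written["embedding_recentered"] = path

        manifest = {
            **{
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "n_samples": X.n_samples,
            "n_features": X.n_features,
            "epochs_run": len(emb.loss_history) - 1,
            "initial_loss": emb.loss_history[0],
            "final_loss": emb.loss_history[-1],
            "root_index": root_index,
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = path
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise
    return written
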