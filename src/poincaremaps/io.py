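"""Readers, writers and preprocessing helpers.

Delimited text (CSV/TSV; samples in rows, header of feature names, first
column sample ids) and Matrix Market with sidecar row/column name files
are supported.  Preprocessing follows standard single-cell practice:
datasets wider than 100 features are reduced to principal components
(default 100), narrower ones are z-scored per feature.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .graph import ExpressionMatrix
from .hyperbolic import PoincareEmbedding

logger = logging.getLogger("poincaremaps")


def _read_names(path: Path) -> list[str]:
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def load_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Load a sample-by-feature matrix from CSV, TSV or Matrix Market.

    CSV/TSV: header row of feature names, first column sample ids.
    MTX: sidecar files ``<stem>.rows.txt`` / ``<stem>.cols.txt`` beside the
    matrix hold sample and feature names, one per line.

    Fails loudly on missing files, non-numeric cells, NaNs (naming the
    first offending row and column) and duplicate sample ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input matrix not found: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"NaN in {path} at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        sample_ids = [str(s) for s in df.index]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"duplicate sample ids in {path}")
        return ExpressionMatrix(values=values, sample_ids=sample_ids,
                                feature_ids=[str(c) for c in df.columns])
    if format == "mtx":
        mat = scipy.io.mmread(path)
        values = mat.toarray() if sp.issparse(mat) else np.asarray(mat)
        rows = path.parent / (path.stem + ".rows.txt")
        cols = path.parent / (path.stem + ".cols.txt")
        if not rows.exists() or not cols.exists():
            raise FileNotFoundError(
                f"MTX input needs sidecar name files {rows.name} and {cols.name}"
            )
        return ExpressionMatrix(
            values=np.asarray(values, dtype=float),
            sample_ids=_read_names(rows),
            feature_ids=_read_names(cols),
        )
    raise ValueError(f"unknown format {format!r}; expected csv, tsv or mtx")


def load_labels(path: str | Path) -> pd.Series:
    """Per-sample labels: two-column delimited file (sample id, label)."""
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0]


def preprocess(X: ExpressionMatrix, n_pcs: int | None = None) -> ExpressionMatrix:
    """Reduce to principal components, or z-score narrow matrices.

    Nearest-neighbor manifold learning suffers from the curse of
    dimensionality, so matrices with more than 100 features default to
    their top 100 principal components.  Matrices with <= 100 features are
    mean-variance normalized per feature instead (constant features are
    left centered with a warning).  An explicit ``n_pcs`` always forces
    PCA.  Deterministic: PCA uses the full SVD solver.
    """
    n, p = X.values.shape
    if n_pcs is not None:
        if not 1 <= n_pcs < min(n, p) + 1:
            raise ValueError(f"n_pcs must be in [1, min(n, p)] = [1, {min(n, p)}], got {n_pcs}")
        return _pca(X, n_pcs)
    if p > 100:
        return _pca(X, min(100, n - 1, p))
    values = X.values - X.values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        names = [X.feature_ids[j] for j in np.where(constant)[0]]
        logger.warning("constant features left centered (no variance scaling): %s", names)
    sd = np.where(constant, 1.0, sd)
    return ExpressionMatrix(values=values / sd, sample_ids=list(X.sample_ids),
                            feature_ids=list(X.feature_ids))


def _pca(X: ExpressionMatrix, n_pcs: int) -> ExpressionMatrix:
    model = PCA(n_components=n_pcs, svd_solver="full")
    scores = model.fit_transform(X.values)
    return ExpressionMatrix(
        values=scores,
        sample_ids=list(X.sample_ids),
        feature_ids=[f"PC{j + 1}" for j in range(n_pcs)],
    )


def write_embedding(path: str | Path, Y: PoincareEmbedding, sample_ids: list[str]) -> None:
    """Write the embedding as delimited text: sample_id, y1, y2.

    Coordinates use full double precision (repr round-trip) so rerunning
    an identical configuration produces byte-identical output.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id,y1,y2\n")
        for sid, (a, b) in zip(sample_ids, Y.Y):
            fh.write(f"{sid},{float(a)!r},{float(b)!r}\n")


def load_embedding(path: str | Path, gamma: float = 2.0) -> tuple[PoincareEmbedding, list[str]]:
    """Read an embedding written by :func:`write_embedding`."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    emb = PoincareEmbedding(Y=df[["y1", "y2"]].to_numpy(float), gamma=gamma)
    return emb, [str(s) for s in df.index]


def write_vector(path: str | Path, values: np.ndarray, sample_ids: list[str], name: str) -> None:
    """One value per sample, keyed by sample id."""
    pd.Series(values, index=pd.Index(sample_ids, name="sample_id"), name=name).to_csv(path)
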