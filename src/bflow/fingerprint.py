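"""Behavioral flow fingerprinting: 2D embedding of transition matrices.

Each recording's (stabilized) transition matrix is flattened row-major
into an NC²-vector and projected to two dimensions with UMAP, giving one
point per animal.  Stabilizing against each experiment's internal
control group first makes embeddings comparable across experiments.
Group summaries report the per-group mean and standard error on both
axes (the crossbars of the fingerprint plots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from bflow.flow import StabilizedTransitionMatrix, TransitionMatrix


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # index recording_id, columns dim1, dim2
    seed: int
    n_neighbors: int
    min_dist: float


class FlowEmbedding(BaseEstimator):
    """Seeded UMAP projection of flattened transition matrices to 2D."""

    def __init__(self, n_neighbors: int = 15, min_dist: float = 0.1,
                 metric: str = "euclidean", random_state: int = 42):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.metric = metric
        self.random_state = random_state

    def fit_transform(self, X, y=None):
        import umap  # deferred: numba compilation is slow at import time

        X = np.asarray(X, dtype=float)
        if X.shape[0] < 4:
            raise ValueError("need at least 4 samples to embed")
        if X.shape[0] <= self.n_neighbors:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} requires more than "
                f"{self.n_neighbors} samples ({X.shape[0]} given); reduce "
                f"n_neighbors to at most {X.shape[0] - 1}")
        reducer = umap.UMAP(n_components=2, n_neighbors=self.n_neighbors,
                            min_dist=self.min_dist, metric=self.metric,
                            random_state=self.random_state)
        self.embedding_ = reducer.fit_transform(X)
        return self.embedding_


def _flatten(matrices) -> tuple[np.ndarray, list[str]]:
    rows, ids = [], []
    for m in matrices:
        vals = m.values if isinstance(m, StabilizedTransitionMatrix) else m.counts
        rows.append(np.asarray(vals, dtype=float).ravel())
        ids.append(m.recording_id)
    return np.asarray(rows), ids


def bff_embed(matrices, seed: int = 42, n_neighbors: int = 15,
              min_dist: float = 0.1) -> EmbeddingResult:
    """Embed a set of (stabilized) transition matrices into 2D.

    Deterministic for fixed inputs, seed and hyperparameters.  Matrices
    are flattened row-major including the structurally zero diagonal
    (which contributes nothing to distances).
    """
    X, ids = _flatten(matrices)
    emb = FlowEmbedding(n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed).fit_transform(X)
    coords = pd.DataFrame(emb, index=ids, columns=["dim1", "dim2"])
    return EmbeddingResult(coords=coords, seed=seed, n_neighbors=n_neighbors,
                           min_dist=min_dist)


def group_summary(embedding: EmbeddingResult, assignment: dict) -> pd.DataFrame:
    """Per-group mean and s.e.m. of both embedding axes.

    ``assignment`` maps recording_id -> group label.  Singleton groups
    get an undefined (NaN) standard error.
    """
    coords = embedding.coords
    missing = [rid for rid in coords.index if rid not in assignment]
    if missing:
        raise ValueError(f"unlabeled recordings: {missing}")
    groups = pd.Series({rid: assignment[rid] for rid in coords.index})
    rows = []
    for g, sub in coords.groupby(groups):
        n = len(sub)
        sem = sub.std(ddof=1) / np.sqrt(n) if n > 1 else \
            pd.Series(np.nan, index=sub.columns)
        rows.append({"group": g, "n": n,
                     "mean_dim1": sub["dim1"].mean(),
                     "mean_dim2": sub["dim2"].mean(),
                     "sem_dim1": sem["dim1"], "sem_dim2": sem["dim2"]})
    return pd.DataFrame(rows).set_index("group")
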