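"""Behavioral clustering: subset assembly, k-means, cluster-count selection.

Frames are clustered in the temporally-expanded feature space.  A random
subset of recordings per experiment is pooled into one matrix, z-scored
across columns, and k-means clustered; the fitted column standardizer is
persisted with the model so that new recordings are projected into
exactly the training space before nearest-center assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

from bflow.features import TemporalFeatureMatrix
from bflow.flow import LabelSequence


class SamplingError(ValueError):
    pass


@dataclass
class ClusteringSubset:
    """Pooled training rows sampled per experiment, with provenance."""

    recording_ids: list[str]
    X: np.ndarray  # (sum N') x (m*t)
    provenance: dict[str, list[str]]  # experiment -> sampled recording ids
    row_recording: np.ndarray  # recording id per row
    seed: int

    @property
    def s(self) -> int:
        return len(self.recording_ids)


def assemble_clustering_subset(
        experiments: dict[str, list[TemporalFeatureMatrix]],
        n_per_experiment: int = 20, seed: int = 0) -> ClusteringSubset:
    """Sample ``n_per_experiment`` recordings per experiment and pool rows.

    Sampling is reproducible given ``seed``; sampling the full set of an
    experiment is allowed (subset == everything).
    """
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    provenance: dict[str, list[str]] = {}
    blocks: list[np.ndarray] = []
    row_rec: list[np.ndarray] = []
    for exp in sorted(experiments):
        recs = experiments[exp]
        if len(recs) < n_per_experiment:
            raise SamplingError(
                f"experiment {exp!r} has {len(recs)} recordings, "
                f"need {n_per_experiment}")
        idx = rng.choice(len(recs), size=n_per_experiment, replace=False)
        chosen = [recs[i] for i in sorted(idx)]
        provenance[exp] = [r.recording_id for r in chosen]
        for r in chosen:
            ids.append(r.recording_id)
            blocks.append(r.values)
            row_rec.append(np.repeat(r.recording_id, r.values.shape[0]))
    return ClusteringSubset(recording_ids=ids, X=np.vstack(blocks),
                            provenance=provenance,
                            row_recording=np.concatenate(row_rec), seed=seed)


class BehaviorKMeans(BaseEstimator, ClusterMixin):
    """K-means over standardized expanded features, persisting the scaler.

    Columns are z-scored on the training data; zero-variance columns are
    mapped to 0 (kept, not dropped, so the feature width is preserved for
    the downstream classifier).  ``predict`` always standardizes with the
    *fitted* statistics, guaranteeing train/apply consistency.

    Parameters
    ----------
    n_clusters : cluster count NC (>= 2).
    n_init : number of seeded k-means++ restarts; best inertia kept.
    random_state : seed for centroid initialization.
    """

    def __init__(self, n_clusters: int = 25, n_init: int = 3,
                 random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] < self.n_clusters:
            raise ValueError("fewer rows than clusters")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0)
        self.zero_variance_ = self.sds_ == 0
        Xs = self._standardize(X)
        if np.unique(Xs, axis=0).shape[0] < self.n_clusters:
            raise ValueError("fewer distinct rows than clusters")
        km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                    random_state=self.random_state)
        self.labels_ = km.fit_predict(Xs)
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = km.inertia_
        return self

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        sds = np.where(self.zero_variance_, 1.0, self.sds_)
        Xs = (X - self.means_) / sds
        Xs[:, self.zero_variance_] = 0.0
        return Xs

    def transform(self, X):
        """Standardize rows into the fitted training space."""
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.means_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.means_.shape[0]}")
        return self._standardize(X)

    def predict(self, X):
        """Nearest-center labels (Euclidean); ties break to the lowest id."""
        Xs = self.transform(X)
        d2 = ((Xs[:, None, :] - self.cluster_centers_[None]) ** 2).sum(-1) \
            if Xs.shape[0] * self.n_clusters * Xs.shape[1] < 2_000_000 else None
        if d2 is None:
            # ||x-c||^2 = ||x||^2 - 2 x.c + ||c||^2; argmin ties -> first index
            d2 = (-2 * Xs @ self.cluster_centers_.T
                  + (self.cluster_centers_ ** 2).sum(1)[None])
        return np.argmin(d2, axis=1)


def fit_kmeans(subset: ClusteringSubset, k: int, seed: int = 0,
               n_init: int = 3) -> BehaviorKMeans:
    """Fit :class:`BehaviorKMeans` on a pooled clustering subset."""
    return BehaviorKMeans(n_clusters=k, n_init=n_init,
                          random_state=seed).fit(subset.X)


def assign_clusters(model: BehaviorKMeans,
                    X: TemporalFeatureMatrix) -> LabelSequence:
    """Label every row of an expanded feature matrix by nearest center."""
    labels = model.predict(X.values)
    return LabelSequence(recording_id=X.recording_id,
                         labels=labels,
                         alphabet=np.arange(model.n_clusters),
                         fps=X.fps, frame_offset=X.frame_offset)


def select_cluster_count(proportions, coverage: float = 0.95) -> int:
    """Smallest number of (largest) clusters covering ``coverage`` of frames.

    Proportions are sorted descending and accumulated; the answer is the
    shortest prefix whose cumulative sum reaches the coverage level.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    csum = np.cumsum(np.sort(p)[::-1])
    return int(np.searchsorted(csum, coverage - 1e-12) + 1)
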