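"""Hybrid k-centers/k-medoids discretization of feature trajectories.

Phase 1 seeds k centers by the classic farthest-point (Gonzalez) heuristic,
which guarantees a max point-to-center distance within a factor 2 of the
optimal k-centers radius.  Phase 2 runs medoid-refinement sweeps that swap a
center for a randomly drawn member whenever the within-cluster distortion
(sum of member-to-center distances) drops, then reassigns globally; total
distortion is non-increasing across sweeps.

The metric is Euclidean on the feature vectors by default, with a pluggable
hook for precomputed descriptor metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureTrajectorySet", "ClusterModel", "hybrid_cluster", "assign"]


@dataclass(frozen=True)
class FeatureTrajectorySet:
    """Per-trajectory feature matrices (frames x features) with frame spacing."""

    trajs: list
    frame_time: float
    ids: list

    def __post_init__(self):
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        trajs = [np.atleast_2d(np.asarray(t, dtype=float)) for t in self.trajs]
        dims = {t.shape[1] for t in trajs}
        if len(dims) > 1:
            raise ValueError(f"trajectories disagree on feature dimension: {dims}")
        object.__setattr__(self, "trajs", trajs)

    @property
    def n_features(self) -> int:
        return self.trajs[0].shape[1]

    @property
    def n_frames(self) -> int:
        return sum(len(t) for t in self.trajs)

    def stacked(self) -> np.ndarray:
        return np.vstack(self.trajs)


@dataclass(frozen=True)
class ClusterModel:
    """k cluster centers in feature space.

    centers : (k, n_features) explicit center vectors
    center_frames : list of (trajectory index, frame index) of each medoid
    metric : "euclidean" (the only built-in; `assign` accepts a callable)
    """

    centers: np.ndarray
    center_frames: list
    metric: str = "euclidean"

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _euclidean(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.linalg.norm(points - center[None, :], axis=1)


def hybrid_cluster(
    features: FeatureTrajectorySet,
    k: int,
    n_medoid_sweeps: int = 10,
    seed: int = 0,
    metric=None,
) -> ClusterModel:
    """Cluster all frames into k microstates (k-centers seeding + medoid sweeps).

    `metric` is a pluggable hook: a callable ``(points, center) -> distances``
    over precomputed descriptors (default Euclidean).
    """
    X = features.stacked()
    n = len(X)
    if n == 0:
        raise ValueError("empty feature set")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must lie in [1, {n}]")
    dist = metric or _euclidean
    rng = np.random.default_rng(seed)

    # phase 1: farthest-point seeding
    center_idx = np.empty(k, dtype=np.int64)
    center_idx[0] = rng.integers(n)
    dmin = dist(X, X[center_idx[0]])
    for c in range(1, k):
        center_idx[c] = int(np.argmax(dmin))
        np.minimum(dmin, dist(X, X[center_idx[c]]), out=dmin)

    labels = _assign_labels(X, X[center_idx], dist)

    # phase 2: medoid refinement
    for _ in range(n_medoid_sweeps):
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) <= 1:
                continue
            cand = int(members[rng.integers(len(members))])
            if cand == center_idx[c]:
                continue
            cur = dist(X[members], X[center_idx[c]]).sum()
            new = dist(X[members], X[cand]).sum()
            if new < cur:
                center_idx[c] = cand
        labels = _assign_labels(X, X[center_idx], dist)

    # map flat indices back to (trajectory, frame)
    lengths = np.array([len(t) for t in features.trajs])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    center_frames = []
    for idx in center_idx:
        tr = int(np.searchsorted(offsets, idx, side="right") - 1)
        center_frames.append((tr, int(idx - offsets[tr])))
    return ClusterModel(centers=X[center_idx].copy(), center_frames=center_frames,
                        metric="euclidean" if metric is None else "custom")


def _assign_labels(X: np.ndarray, centers: np.ndarray, dist=None) -> np.ndarray:
    # chunked pairwise distances; argmin takes the lowest index on ties
    labels = np.empty(len(X), dtype=np.int64)
    if dist is not None and dist is not _euclidean:
        D = np.stack([dist(X, c) for c in centers], axis=1)
        return np.argmin(D, axis=1)
    step = max(1, 2_000_000 // max(1, len(centers)))
    for s in range(0, len(X), step):
        block = X[s:s + step]
        d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels[s:s + step] = np.argmin(d2, axis=1)
    return labels


def assign(features: FeatureTrajectorySet, model: ClusterModel, metric=None):
    """Map every frame to its nearest center (ties -> lowest center index)."""
    from .msm import DiscreteTrajectorySet

    if features.n_features != model.centers.shape[1]:
        raise ValueError("feature dimension does not match the cluster model")
    dtrajs = [_assign_labels(t, model.centers, metric) for t in features.trajs]
    return DiscreteTrajectorySet(dtrajs=dtrajs, frame_time=features.frame_time,
                                 n_states=model.k)
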