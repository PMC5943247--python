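"""Spatial cluster identification for localization point clouds.

Two clusterers are provided, both implemented natively and exposed as
scikit-learn style estimators:

* :class:`DBSCANClusterer` — density-based clustering (core points have
  at least ``min_pts`` neighbours within ``eps``, counting themselves;
  clusters are the connected components of the core-point graph; border
  points join the cluster of their lowest-index core neighbour; the rest
  is noise). Deterministic and independent of input order for core
  points; the border rule pins the one ambiguity in the textbook
  definition.

* :class:`CentroidLinkageClusterer` — sequential-recombination
  (jet-style) centroid linkage: repeatedly merge the pair of clusters
  whose centroids are nearest, the centroid being the unweighted mean of
  all member localizations, until the minimum inter-centroid distance
  exceeds the cutoff ``R``; clusters smaller than ``min_count`` are then
  discarded as noise. Ties are broken by the lexicographically smallest
  pair of cluster ids.

Cluster labels are integers ``0..K-1`` ordered by each cluster's first
member record; noise is ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree, ConvexHull, QhullError
from sklearn.base import BaseEstimator, ClusterMixin

NOISE = -1


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of first appearance; noise stays -1."""
    labels = np.full(raw.shape, NOISE, dtype=np.int64)
    mapping = {}
    for i, r in enumerate(raw):
        if r == NOISE:
            continue
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[i] = mapping[r]
    return labels


def _as_xy(X) -> np.ndarray:
    if hasattr(X, "xy"):
        X = X.xy
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or (len(X) and X.shape[1] != 2):
        raise ValueError("expected an (n, 2) array of nm coordinates")
    return X


class DBSCANClusterer(ClusterMixin, BaseEstimator):
    """Density-based spatial clustering with deterministic border rule.

    Parameters
    ----------
    eps : float
        Neighbourhood radius, nm.
    min_pts : int
        Minimum neighbours (including the point itself) for a core point.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster id per record, ``-1`` for noise.
    core_mask_ : ndarray of bool
        True where the record is a core point.
    """

    def __init__(self, eps: float = 100.0, min_pts: int = 10):
        self.eps = eps
        self.min_pts = min_pts

    def fit(self, X, y=None):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        X = _as_xy(X)
        n = len(X)
        if n == 0:
            self.labels_ = np.empty(0, dtype=np.int64)
            self.core_mask_ = np.empty(0, dtype=bool)
            return self
        tree = cKDTree(X)
        neighbors = tree.query_ball_point(X, self.eps)  # includes self
        counts = np.fromiter((len(nb) for nb in neighbors), dtype=np.int64, count=n)
        core = counts >= self.min_pts

        # connected components over core points within eps (union-find)
        parent = np.arange(n)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        core_idx = np.flatnonzero(core)
        for i in core_idx:
            ri = find(i)
            for j in neighbors[i]:
                if core[j]:
                    rj = find(j)
                    if ri != rj:
                        parent[rj] = ri
                        ri = find(i)

        raw = np.full(n, NOISE, dtype=np.int64)
        for i in core_idx:
            raw[i] = find(i)
        # border points: lowest-index core neighbour decides the cluster
        for i in np.flatnonzero(~core):
            cs = [j for j in neighbors[i] if core[j]]
            if cs:
                raw[i] = find(min(cs))
        self.labels_ = _canonical_labels(raw)
        self.core_mask_ = core
        return self


class CentroidLinkageClusterer(ClusterMixin, BaseEstimator):
    """Sequential-recombination centroid linkage with distance cutoff.

    Parameters
    ----------
    R : float
        Stop merging once the nearest pair of centroids is farther than
        this, nm.
    min_count : int
        Final clusters with fewer members become noise.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
    merge_sequence_ : list of (i, j, distance)
        Ids of the merged clusters per step, scipy linkage convention:
        initial clusters are ``0..n-1`` and the cluster created by step
        ``k`` has id ``n + k``; within a pair ``i < j``.
    """

    def __init__(self, R: float = 100.0, min_count: int = 3):
        self.R = R
        self.min_count = min_count

    def fit(self, X, y=None):
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        X = _as_xy(X)
        n = len(X)
        self.merge_sequence_ = []
        if n == 0:
            self.labels_ = np.empty(0, dtype=np.int64)
            return self

        # slot arrays: merging (a, b) reuses slot a, frees slot b
        centroids = X.copy()
        sizes = np.ones(n, dtype=np.int64)
        ids = np.arange(n)                      # external id per live slot
        active = np.ones(n, dtype=bool)
        members: List[List[int]] = [[i] for i in range(n)]
        # full symmetric distance matrix over slots, inf where inactive
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)

        next_id = n
        n_active = n
        while n_active > 1:
            flat = np.argmin(dist)
            a, b = np.unravel_index(flat, dist.shape)
            d = dist[a, b]
            if not np.isfinite(d) or d > self.R:
                break
            # tie-break: smallest (i, j) external id pair among minima
            ties = np.argwhere(dist == d)
            ties = ties[ties[:, 0] < ties[:, 1]]
            if len(ties) > 1:
                pairs = sorted(
                    (tuple(sorted((ids[p], ids[q]))), (p, q)) for p, q in ties
                )
                a, b = pairs[0][1]
            i_id, j_id = sorted((ids[a], ids[b]))
            self.merge_sequence_.append((int(i_id), int(j_id), float(d)))

            new_centroid = (
                centroids[a] * sizes[a] + centroids[b] * sizes[b]
            ) / (sizes[a] + sizes[b])
            centroids[a] = new_centroid
            sizes[a] += sizes[b]
            members[a] = members[a] + members[b]
            ids[a] = next_id
            next_id += 1
            active[b] = False
            dist[b, :] = np.inf
            dist[:, b] = np.inf
            row = np.sqrt(((centroids[active] - new_centroid) ** 2).sum(-1))
            dist[a, active] = row
            dist[active, a] = row
            dist[a, a] = np.inf
            n_active -= 1

        raw = np.full(n, NOISE, dtype=np.int64)
        for slot in np.flatnonzero(active):
            if sizes[slot] >= self.min_count:
                raw[members[slot]] = slot
        self.labels_ = _canonical_labels(raw)
        return self


def dbscan(table, eps: float, min_pts: int) -> np.ndarray:
    """Label clusters by density; thin wrapper over :class:`DBSCANClusterer`."""
    return DBSCANClusterer(eps=eps, min_pts=min_pts).fit(table).labels_


def centroid_linkage_cluster(table, R: float, min_count: int = 3) -> np.ndarray:
    """Label clusters by sequential recombination with cutoff ``R``."""
    return CentroidLinkageClusterer(R=R, min_count=min_count).fit(table).labels_


@dataclass
class ClusterSummary:
    cluster_id: int
    n_localizations: int
    centroid: Tuple[float, float]
    area: float            # convex hull, nm^2; 0 for degenerate clusters
    radius_gyration: float  # nm


def _hull_area(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # in 2-D, volume is the area
    except QhullError:
        return 0.0  # collinear


def summarize_clusters(table, labels: np.ndarray) -> List[ClusterSummary]:
    """Per-cluster summaries (count, centroid, hull area, R_g); noise skipped."""
    X = _as_xy(table)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels are not aligned with the table")
    out = []
    for cid in np.unique(labels[labels != NOISE]):
        pts = X[labels == cid]
        c = pts.mean(axis=0)
        rg = float(np.sqrt(((pts - c) ** 2).sum(axis=1).mean()))
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                n_localizations=len(pts),
                centroid=(float(c[0]), float(c[1])),
                area=_hull_area(pts),
                radius_gyration=rg,
            )
        )
    return out


def size_survival_curve(
    summaries: Sequence, sizes: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Survival function of cluster sizes.

    ``survival(s)`` is the fraction of clusters with at least ``s``
    localizations, evaluated on the sorted unique sizes; it starts at 1
    and is non-increasing. Accepts either summaries or a raw size array.
    """
    if sizes is None:
        sizes = np.array([s.n_localizations for s in summaries], dtype=float)
    else:
        sizes = np.asarray(sizes, dtype=float)
    if len(sizes) == 0:
        raise ValueError("no clusters to build a survival curve from")
    grid = np.unique(sizes)
    surv = np.array([(sizes >= s).mean() for s in grid])
    return grid, surv
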