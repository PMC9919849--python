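"""Single-plant segmentation: Euclidean clustering with a K-means fallback.

Euclidean clustering groups points that lie within a distance threshold
``r`` of each other — region growing over KD-tree neighborhoods, which is
exactly the connected components of the r-neighborhood graph.  Where plants
grow into each other the merged component is split with seeded Lloyd
K-means.  Merged components are detected automatically from cluster sizes
(the original procedure identified them manually and chose K by eye).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .cloudio import PointCloud

__all__ = [
    "EuclidParams",
    "KMeansParams",
    "ClusterSet",
    "euclidean_cluster",
    "kmeans",
    "detect_merged",
    "segment_plants",
]

log = logging.getLogger(__name__)


@dataclass
class EuclidParams:
    radius: float = 0.05            # r, the neighbor distance threshold (m)
    min_cluster_size: int = 100     # clusters below this are discarded as noise

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class KMeansParams:
    K: int = 2
    max_iter: int = 100
    seed: int = 0
    init: str = "kmeans++"          # or "random"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.init not in ("kmeans++", "random"):
            raise ValueError("init must be 'kmeans++' or 'random'")


@dataclass
class ClusterSet:
    """Disjoint clusters as index arrays into a parent cloud."""

    parent: PointCloud
    members: list[np.ndarray]
    labels: list[str] = field(default_factory=list)
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = [f"cluster_{i:03d}" for i in range(len(self.members))]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)

    def centroid(self, i: int) -> np.ndarray:
        return self.parent.xyz[self.members[i]].mean(axis=0)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([self.centroid(i) for i in range(len(self))]).reshape(-1, 3)

    def points(self, i: int) -> PointCloud:
        return self.parent.subset(self.members[i])


def euclidean_cluster(cloud: PointCloud, params: EuclidParams | None = None) -> ClusterSet:
    """Cluster a cloud into connected components of the r-neighborhood graph.

    Equivalent to KD-tree region growing: seed an unvisited point and absorb
    every point within ``r`` of any member until the component stops growing.
    Components smaller than ``min_cluster_size`` are discarded (their point
    count is recorded in ``n_discarded`` and logged).
    """
    params = params or EuclidParams()
    n = len(cloud)
    if n == 0:
        raise ValueError("cannot cluster an empty cloud")
    pairs = cKDTree(cloud.xyz).query_pairs(params.radius, output_type="ndarray")
    if len(pairs):
        graph = sparse.coo_matrix(
            (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
            shape=(n, n))
        _, comp = sparse.csgraph.connected_components(graph, directed=False)
    else:
        comp = np.arange(n)
    order = np.argsort(comp, kind="stable")
    bounds = np.flatnonzero(np.diff(comp[order])) + 1
    groups = np.split(order, bounds)
    members = []
    discarded = 0
    for g in groups:
        g = np.sort(g)
        if len(g) >= params.min_cluster_size:
            members.append(g)
        else:
            discarded += len(g)
    if discarded:
        log.info("euclidean_cluster: discarded %d points in clusters below "
                 "min size %d", discarded, params.min_cluster_size)
    members.sort(key=lambda g: int(g[0]))
    return ClusterSet(cloud, members, n_discarded=discarded)


def _kmeans_pp_init(xyz: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = len(xyz)
    centers = np.empty((K, 3))
    centers[0] = xyz[rng.integers(n)]
    d2 = ((xyz - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = xyz[rng.integers(n)]
            continue
        centers[k] = xyz[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((xyz - centers[k]) ** 2).sum(axis=1))
    return centers


def kmeans(points: PointCloud | np.ndarray, params: KMeansParams) -> ClusterSet:
    """Seeded Lloyd K-means on 3D points.

    Iterates assign-to-nearest-center / recompute-means until the assignment
    stops changing (or ``max_iter``).  An emptied cluster is re-seeded at the
    point farthest from its nearest center.  Deterministic given the seed.
    """
    cloud = points if isinstance(points, PointCloud) else PointCloud(points)
    xyz = cloud.xyz
    n = len(xyz)
    if params.K > n:
        raise ValueError(f"K={params.K} exceeds point count {n}")
    rng = np.random.default_rng(params.seed)
    if params.init == "kmeans++":
        centers = _kmeans_pp_init(xyz, params.K, rng)
    else:
        centers = xyz[rng.choice(n, size=params.K, replace=False)]
    labels = np.full(n, -1)
    for _ in range(params.max_iter):
        d2 = ((xyz[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(params.K):
            mask = labels == k
            if mask.any():
                centers[k] = xyz[mask].mean(axis=0)
            else:
                centers[k] = xyz[d2.min(axis=1).argmax()]
    members = [np.flatnonzero(labels == k) for k in range(params.K)]
    members = [m for m in members if len(m)]
    members.sort(key=lambda g: int(g[0]))
    return ClusterSet(cloud, members)


def detect_merged(clusters: ClusterSet, expected_count: int | None = None,
                  merge_factor: float = 1.8) -> list[tuple[int, int]]:
    """Flag clusters that look like several merged plants.

    Returns ``(cluster_index, K_split)`` pairs.  With ``expected_count`` and
    fewer clusters than expected, the largest clusters are flagged with
    ``K_split = round(size / median size)`` until the counts reconcile;
    without it, any cluster larger than ``merge_factor`` times the median is
    flagged with the same rule.
    """
    if len(clusters) == 0:
        raise ValueError("need at least one cluster")
    sizes = clusters.sizes
    median = float(np.median(sizes))
    flags: list[tuple[int, int]] = []
    if expected_count is not None:
        if len(clusters) >= expected_count:
            return []
        deficit = expected_count - len(clusters)
        order = np.argsort(-sizes, kind="stable")
        for i in order:
            k_split = max(2, int(round(sizes[i] / median)))
            flags.append((int(i), k_split))
            deficit -= k_split - 1
            if deficit <= 0:
                break
        return flags
    for i, s in enumerate(sizes):
        if s > merge_factor * median:
            flags.append((i, max(2, int(round(s / median)))))
    return flags


def segment_plants(cloud: PointCloud, eparams: EuclidParams | None = None,
                   kparams_base: KMeansParams | None = None,
                   expected_count: int | None = None,
                   order_axis: np.ndarray | None = None,
                   lateral_axis: np.ndarray | None = None) -> ClusterSet:
    """Segment a ground-free cloud into single plants.

    Euclidean clustering first; clusters flagged by :func:`detect_merged`
    are split with K-means (K from the size rule) and replaced.  Final
    clusters are labeled ``plant_001`` ... in ascending order of their
    centroid's travel-axis coordinate (``order_axis``, default +z, the raw
    sensor travel axis), with the lateral coordinate as tie-break.
    """
    eparams = eparams or EuclidParams()
    kparams_base = kparams_base or KMeansParams()
    cs = euclidean_cluster(cloud, eparams)
    if len(cs) == 0:
        raise ValueError("no clusters above min size — nothing to segment")
    flags = detect_merged(cs, expected_count)
    if expected_count is not None and len(cs) > expected_count:
        log.warning("segment_plants: found %d clusters, expected %d; no split "
                    "performed", len(cs), expected_count)
    members = list(cs.members)
    for ci, k_split in flags:
        sub = cloud.subset(members[ci])
        kp = KMeansParams(K=k_split, max_iter=kparams_base.max_iter,
                          seed=kparams_base.seed, init=kparams_base.init)
        split = kmeans(sub, kp)
        global_members = [members[ci][m] for m in split.members]
        members[ci] = global_members[0]
        members.extend(global_members[1:])
    order_axis = np.asarray(order_axis if order_axis is not None else [0.0, 0.0, 1.0])
    lateral_axis = np.asarray(lateral_axis if lateral_axis is not None else [1.0, 0.0, 0.0])
    cents = np.array([cloud.xyz[m].mean(axis=0) for m in members])
    keys = np.column_stack([cents @ order_axis, cents @ lateral_axis])
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    members = [members[i] for i in order]
    labels = [f"plant_{i + 1:03d}" for i in range(len(members))]
    return ClusterSet(cloud, members, labels=labels, n_discarded=cs.n_discarded)
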