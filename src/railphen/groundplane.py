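"""Outlier removal, RANSAC ground-plane detection, and horizontal calibration.

Statistical outlier removal (SOR) scores every point by its mean distance to
its k nearest neighbors and removes points whose score exceeds the global
mean by more than ``alpha`` standard deviations.  The ground is then found by
RANSAC: repeatedly fit the exact plane through three random points,

    A = (y2-y1)(z3-z1) - (z2-z1)(y3-y1)
    B = (z2-z1)(x3-x1) - (x2-x1)(z3-z1)
    C = (x2-x1)(y3-y1) - (y2-y1)(x3-x1)
    D = -(A x1 + B y1 + C z1),

score it by the number of points whose point-plane distance
``|Ax+By+Cz+D| / sqrt(A²+B²+C²)`` is within a threshold, and keep the model
with the most inliers.  Horizontal calibration finally rotates the fitted
ground normal onto the vertical axis (0,0,1) by the axis-angle (Rodrigues)
rotation about their cross product, so that plant heights can be read off z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import PointCloud
from .registration import RigidTransform

__all__ = [
    "SORParams",
    "RansacParams",
    "PlaneModel",
    "sor_filter",
    "plane_from_points",
    "point_plane_distance",
    "ransac_plane",
    "orient_plane",
    "calibrate_horizontal",
    "DegenerateSampleError",
]


class DegenerateSampleError(ValueError):
    """Three sampled points were (near-)collinear: no unique plane."""


@dataclass
class SORParams:
    k_neighbors: int = 20
    std_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be positive")


@dataclass
class RansacParams:
    iterations: int = 1000
    distance_threshold: float = 0.01    # ΔT1 (m)
    seed: int = 0
    refit: bool = True                  # least-squares polish on the winner's inliers

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")


@dataclass
class PlaneModel:
    """Normalized plane Ax + By + Cz + D = 0 with unit normal (A, B, C)."""

    A: float
    B: float
    C: float
    D: float
    inlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        norm = float(np.sqrt(self.A ** 2 + self.B ** 2 + self.C ** 2))
        if norm < 1e-300:
            raise ValueError("zero normal vector")
        self.A, self.B, self.C, self.D = (v / norm for v in (self.A, self.B, self.C, self.D))

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    @property
    def n_inliers(self) -> int:
        return 0 if self.inlier_mask is None else int(self.inlier_mask.sum())

    def canonicalized(self) -> "PlaneModel":
        """Flip the sign so C >= 0 (then B >= 0, then A >= 0 on ties)."""
        for lead in (self.C, self.B, self.A):
            if abs(lead) > 1e-12:
                sign = 1.0 if lead > 0 else -1.0
                break
        else:
            sign = 1.0
        return PlaneModel(sign * self.A, sign * self.B, sign * self.C, sign * self.D,
                          self.inlier_mask)

    def flipped(self) -> "PlaneModel":
        return PlaneModel(-self.A, -self.B, -self.C, -self.D, self.inlier_mask)

    def signed_distance(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.normal + self.D

    def z_at(self, x: float, y: float) -> float:
        """Plane elevation z(x, y); requires a non-horizontal-normal plane."""
        if abs(self.C) < 1e-12:
            raise ValueError("plane is vertical; z(x, y) undefined")
        return -(self.A * x + self.B * y + self.D) / self.C

    def transformed(self, transform: RigidTransform) -> "PlaneModel":
        """Plane coefficients after applying a rigid motion to the cloud."""
        n = transform.R @ self.normal
        d = self.D - float(n @ transform.t)
        return PlaneModel(n[0], n[1], n[2], d, self.inlier_mask)


def sor_filter(cloud: PointCloud, params: SORParams | None = None):
    """Statistical outlier removal.

    Returns ``(filtered_cloud, removed_mask)`` where ``removed_mask`` is True
    for discarded points; survivor order is preserved.  The cutoff is
    one-sided (mean k-NN distance above ``mu + alpha * sigma``): an unusually
    *small* neighbor distance never indicates a sparse outlier.
    """
    params = params or SORParams()
    n = len(cloud)
    if n <= params.k_neighbors:
        raise ValueError(f"cloud size {n} must exceed k_neighbors={params.k_neighbors}")
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=params.k_neighbors + 1)
    mean_dist = dist[:, 1:].mean(axis=1)        # drop self-match
    mu = mean_dist.mean()
    sigma = mean_dist.std()
    removed = mean_dist > mu + params.std_ratio * sigma
    return cloud.subset(~removed), removed


def plane_from_points(p1, p2, p3) -> PlaneModel:
    """Exact plane through three points, normalized and canonicalized."""
    p1, p2, p3 = (np.asarray(p, dtype=float).reshape(3) for p in (p1, p2, p3))
    (x1, y1, z1), (x2, y2, z2), (x3, y3, z3) = p1, p2, p3
    A = (y2 - y1) * (z3 - z1) - (z2 - z1) * (y3 - y1)
    B = (z2 - z1) * (x3 - x1) - (x2 - x1) * (z3 - z1)
    C = (x2 - x1) * (y3 - y1) - (y2 - y1) * (x3 - x1)
    scale = max(np.linalg.norm(p2 - p1) * np.linalg.norm(p3 - p1), 1.0)
    if np.sqrt(A * A + B * B + C * C) < 1e-12 * scale:
        raise DegenerateSampleError("collinear sample points")
    D = -(A * x1 + B * y1 + C * z1)
    return PlaneModel(A, B, C, D).canonicalized()


def point_plane_distance(p, plane: PlaneModel) -> float | np.ndarray:
    """Unsigned distance from point(s) to a normalized plane (m)."""
    d = np.abs(plane.signed_distance(p))
    return float(d[0]) if np.asarray(p).ndim == 1 else d


def ransac_plane(cloud: PointCloud, params: RansacParams | None = None) -> PlaneModel:
    """Seeded RANSAC ground detection.

    Each iteration samples 3 distinct points, builds their exact plane, and
    counts points within the distance threshold; the max-inlier model wins
    (first winner kept on ties).  Deterministic given the seed.  With
    ``refit`` the winning model is polished by a least-squares plane fit on
    its inliers (SVD of the centered inlier coordinates) and the mask is
    recomputed; disable to return the raw minimal-sample model.
    """
    params = params or RansacParams()
    xyz = cloud.xyz
    n = len(cloud)
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(params.seed)
    best_count = -1
    best_plane: PlaneModel | None = None
    best_mask: np.ndarray | None = None
    for _ in range(params.iterations):
        idx = rng.choice(n, size=3, replace=False)
        try:
            plane = plane_from_points(*xyz[idx])
        except DegenerateSampleError:
            continue
        dist = np.abs(xyz @ plane.normal + plane.D)
        mask = dist <= params.distance_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_plane, best_mask = count, plane, mask
    if best_plane is None:
        raise DegenerateSampleError("all RANSAC samples were degenerate")
    if params.refit and best_count >= 3:
        pts = xyz[best_mask]
        centroid = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
        normal = Vt[2]
        D = -float(normal @ centroid)
        plane = PlaneModel(normal[0], normal[1], normal[2], D).canonicalized()
        dist = np.abs(xyz @ plane.normal + plane.D)
        mask = dist <= params.distance_threshold
        best_plane, best_mask = plane, mask
    best_plane.inlier_mask = best_mask
    return best_plane


def orient_plane(plane: PlaneModel, toward_xyz: np.ndarray) -> PlaneModel:
    """Flip the plane normal so it points toward the given points.

    The sign convention of a fitted ground plane is arbitrary; before
    horizontal calibration the normal must point toward the crop side (the
    off-plane points), so that "up" ends up at +z.
    """
    mean_side = float(np.mean(plane.signed_distance(toward_xyz)))
    return plane.flipped() if mean_side < 0 else plane


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rodrigues rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antipodal: conventional 180° rotation about the x axis (or y when
        # a is itself along x)
        axis = np.array([1.0, 0.0, 0.0])
        if abs(a @ axis) > 1 - 1e-9:
            axis = np.array([0.0, 1.0, 0.0])
        axis = axis - (axis @ a) * a
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (s * s))


def calibrate_horizontal(cloud: PointCloud, plane: PlaneModel):
    """Rotate the cloud so the plane normal becomes vertical (0, 0, 1).

    Returns ``(rotated_cloud, transform)`` with a pure rotation (t = 0).
    The stored normal is rotated as given — orient it with
    :func:`orient_plane` first if its sign is unknown.
    """
    R = _rotation_between(plane.normal, np.array([0.0, 0.0, 1.0]))
    transform = RigidTransform(R, np.zeros(3))
    return cloud.transformed(R, np.zeros(3)), transform
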