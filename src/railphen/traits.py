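"""Per-plant trait extraction and agreement metrics.

Plant height follows h = Z_max - Z_min - h_p: the highest crop point minus
the ground-plane elevation under the plant, minus the known pot height.
Maximum crown width L is the diameter of the plant's footprint: project the
(pot-free) cluster to the xy plane, take the convex hull, and find the
farthest antipodal vertex pair with Shamos' rotating-calipers sweep, which
is linear in the hull size.  Agreement with reference measurements is
reported as the R² of a linear fit and the RMSE of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .cloudio import PointCloud
from .groundplane import PlaneModel

__all__ = [
    "Hull2D",
    "EvalReport",
    "CrownResult",
    "HeightResult",
    "plant_height",
    "project_xy",
    "convex_hull",
    "calipers_diameter",
    "max_crown_width",
    "evaluate",
]


@dataclass
class Hull2D:
    """Convex polygon vertices in counter-clockwise order.

    Degenerate inputs yield degenerate hulls: one vertex for a single point,
    the two extremes for collinear input.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 1:
            raise ValueError("hull needs at least one vertex")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class EvalReport:
    r_squared: float
    rmse: float
    n: int
    slope: float
    intercept: float

    def as_dict(self) -> dict:
        return {"r_squared": self.r_squared, "rmse": self.rmse, "n": self.n,
                "slope": self.slope, "intercept": self.intercept}


class HeightResult(NamedTuple):
    height: float
    z_max: float
    z_min: float
    valid: bool


class CrownResult(NamedTuple):
    width: float
    pair: tuple[np.ndarray, np.ndarray] | None
    n_used: int
    valid: bool


def plant_height(cluster: PointCloud | np.ndarray, plane: PlaneModel,
                 hp: float) -> HeightResult:
    """h = Z_max - Z_min - h_p on a horizontally calibrated cluster.

    Z_max is the literal cluster maximum z; Z_min is the ground-plane
    elevation evaluated at the cluster's xy centroid (robust to residual
    tilt).  A non-positive h is returned flagged invalid, not clamped.
    """
    xyz = cluster.xyz if isinstance(cluster, PointCloud) else np.asarray(cluster)
    if len(xyz) == 0:
        raise ValueError("empty cluster")
    if hp < 0:
        raise ValueError("pot height must be non-negative")
    z_max = float(xyz[:, 2].max())
    cx, cy = xyz[:, 0].mean(), xyz[:, 1].mean()
    z_min = plane.z_at(cx, cy)
    h = z_max - z_min - hp
    return HeightResult(h, z_max, z_min, valid=h > 0)


def project_xy(cluster: PointCloud | np.ndarray) -> np.ndarray:
    """Vertical projection: drop z, keeping count and duplicates."""
    xyz = cluster.xyz if isinstance(cluster, PointCloud) else np.asarray(cluster)
    if len(xyz) == 0:
        raise ValueError("empty cluster")
    return np.array(xyz[:, :2], dtype=float)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points2d: np.ndarray) -> Hull2D:
    """Monotone-chain convex hull, CCW, collinear edge points dropped."""
    pts = np.asarray(points2d, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    uniq = np.unique(pts, axis=0)       # lexicographic sort + dedupe
    if len(uniq) == 1:
        return Hull2D(uniq)
    lower: list[np.ndarray] = []
    for p in uniq:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in uniq[::-1]:
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    verts = lower[:-1] + upper[:-1]
    if len(verts) < 2:      # all collinear: keep the two extremes
        verts = [uniq[0], uniq[-1]]
    return Hull2D(np.array(verts))


def calipers_diameter(hull: Hull2D):
    """Shamos rotating-calipers diameter of a convex polygon.

    Sweeps a pair of parallel supporting lines around the polygon, visiting
    every antipodal vertex pair in a single linear pass, and returns the
    largest pairwise distance ``L`` with the attaining pair.  One-vertex
    hulls give L = 0; two-vertex hulls their separation.
    """
    v = hull.vertices
    n = len(v)
    if n == 1:
        return 0.0, (v[0], v[0])
    if n == 2:
        return float(np.linalg.norm(v[1] - v[0])), (v[0], v[1])

    def area2(i, j, k):
        return _cross(v[i], v[j], v[k])

    best2 = -1.0
    best_pair = (v[0], v[1])
    j = 1
    for i in range(n):
        i1 = (i + 1) % n
        # advance the opposite vertex while the triangle area (distance to
        # the directed edge i->i+1) keeps growing
        while area2(i, i1, (j + 1) % n) > area2(i, i1, j):
            j = (j + 1) % n
        for cand in (j, (j + 1) % n):
            d2 = float(((v[cand] - v[i]) ** 2).sum())
            if d2 > best2:
                best2 = d2
                best_pair = (v[i], v[cand])
            d2 = float(((v[cand] - v[i1]) ** 2).sum())
            if d2 > best2:
                best2 = d2
                best_pair = (v[i1], v[cand])
    return float(np.sqrt(best2)), best_pair


def max_crown_width(cluster: PointCloud | np.ndarray, plane: PlaneModel,
                    hp: float, exclude_pot: bool = True) -> CrownResult:
    """Maximum crown width L of a calibrated single-plant cluster.

    With ``exclude_pot`` (default) points at or below the pot rim
    (z <= Z_min + h_p) are dropped first, so a wide pot cannot define L;
    the rest is projected to xy, hulled, and measured with rotating
    calipers.  No points above the rim flags the result invalid.
    """
    xyz = cluster.xyz if isinstance(cluster, PointCloud) else np.asarray(cluster)
    if len(xyz) == 0:
        raise ValueError("empty cluster")
    if exclude_pot:
        cx, cy = xyz[:, 0].mean(), xyz[:, 1].mean()
        rim = plane.z_at(cx, cy) + hp
        keep = xyz[:, 2] > rim
        if not keep.any():
            return CrownResult(float("nan"), None, 0, valid=False)
        xyz = xyz[keep]
    L, pair = calipers_diameter(convex_hull(project_xy(xyz)))
    return CrownResult(L, pair, len(xyz), valid=True)


def evaluate(estimated, measured) -> EvalReport:
    """Agreement of estimates with reference values.

    Ordinary least squares of estimated on measured gives slope, intercept
    and R²; RMSE is computed on the raw paired differences (not regression
    residuals).
    """
    est = np.asarray(estimated, dtype=float).reshape(-1)
    meas = np.asarray(measured, dtype=float).reshape(-1)
    if est.shape != meas.shape:
        raise ValueError("estimated and measured must have equal length")
    if len(est) < 2:
        raise ValueError("need at least 2 pairs")
    if np.ptp(meas) == 0:
        raise ValueError("measured values are constant; R^2 undefined")
    slope, intercept = np.polyfit(meas, est, 1)
    fitted = slope * meas + intercept
    ss_res = float(((est - fitted) ** 2).sum())
    ss_tot = float(((est - est.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(np.mean((est - meas) ** 2)))
    return EvalReport(r_squared=r2, rmse=rmse, n=len(est),
                      slope=float(slope), intercept=float(intercept))
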