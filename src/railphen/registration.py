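"""Block registration: coarse stop-spacing alignment, ICP refinement, merging.

Acquisition stops are spaced a known 190 cm apart, so block ``k`` is first
coarse-aligned by translating it ``(k-1) * spacing`` along the travel axis.
The residual stop-pose error is removed with point-to-point ICP: alternate
(1) nearest-neighbor correspondences between the clouds, gated by a maximum
correspondence distance, and (2) the closed-form rigid least-squares update
(centroid subtraction, cross-covariance SVD with a reflection guard), until
the mean correspondence distance d falls below a threshold, stops changing,
or the iteration cap is reached.  Refined blocks are appended to the growing
strip cloud in acquisition order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloudio import PointCloud

__all__ = [
    "RigidTransform",
    "ICPParams",
    "ICPResult",
    "MergeResult",
    "coarse_offset",
    "find_correspondences",
    "estimate_transform",
    "icp",
    "merge_blocks",
]

log = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` with R in SO(3)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=np.float64).reshape(3)
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R is a reflection (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the motion applying ``other`` first, then ``self``."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def rotation_angle(self) -> float:
        """Rotation angle in radians."""
        c = (np.trace(self.R) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.t
        return m


@dataclass
class ICPParams:
    """Convergence and gating parameters.

    The source never states its threshold or iteration cap; these defaults
    are the package's own choices.
    """

    d_threshold: float = 0.001      # convergence mean distance (m)
    max_iterations: int = 50
    max_corr_dist: float = 0.05     # correspondence gate (m)
    stall_delta: float = 1e-6       # stop when |Δd| falls below this (m)
    trim_factor: float = 3.0        # drop pairs beyond this multiple of the
                                    # median pair distance (0 disables); robust
                                    # to spurious pairs at the overlap boundary
    trim_floor: float = 0.005       # never trim below this distance (m), so the
                                    # estimation set keeps a representative mass
                                    # when duplicate returns make the median tiny

    def __post_init__(self) -> None:
        if self.d_threshold <= 0 or self.max_iterations <= 0 or self.max_corr_dist <= 0:
            raise ValueError("ICP parameters must be positive")


@dataclass
class ICPResult:
    transform: RigidTransform
    final_d: float
    iterations: int
    converged: bool
    n_pairs: int = 0
    stalled: bool = False           # terminated on |Δd| < stall_delta
    message: str = ""


@dataclass
class MergeResult:
    cloud: PointCloud
    transforms: list[RigidTransform]    # total transform applied to each block
    icp_results: list[ICPResult | None] = field(default_factory=list)
    fallbacks: list[int] = field(default_factory=list)


def coarse_offset(k: int, spacing: float = 1.90, travel_axis: str = "z") -> np.ndarray:
    """Coarse-alignment translation of the k-th block (1-based), (k-1)*spacing
    along the travel axis — the 190 cm stop spacing by default."""
    if k < 1:
        raise ValueError("block index k must be >= 1")
    d = np.zeros(3)
    d[_AXES[travel_axis]] = (k - 1) * spacing
    return d


def find_correspondences(source: PointCloud | np.ndarray,
                         target: PointCloud | np.ndarray,
                         max_corr_dist: float):
    """Nearest-source-point correspondences for every target point.

    Returns ``(i_target, j_source, distance)`` arrays with pairs beyond
    ``max_corr_dist`` excluded (possibly empty).
    """
    src = source.xyz if isinstance(source, PointCloud) else np.asarray(source)
    tgt = target.xyz if isinstance(target, PointCloud) else np.asarray(target)
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("both clouds must be non-empty")
    dist, j = cKDTree(src).query(tgt, k=1)
    keep = dist <= max_corr_dist
    i = np.flatnonzero(keep)
    return i, j[keep], dist[keep]


def estimate_transform(i_target: np.ndarray, j_source: np.ndarray,
                       source: PointCloud | np.ndarray,
                       target: PointCloud | np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid motion mapping source onto target.

    Minimizes the mean squared correspondence error E(R, t) =
    (1/n) Σ ||q_i - (R p_i + t)||² over proper rotations via centroid
    subtraction and SVD of the cross-covariance, with a reflection guard
    forcing det(R) = +1.
    """
    src = source.xyz if isinstance(source, PointCloud) else np.asarray(source)
    tgt = target.xyz if isinstance(target, PointCloud) else np.asarray(target)
    p = src[np.asarray(j_source)]
    q = tgt[np.asarray(i_target)]
    if len(p) < 3:
        raise ValueError("need at least 3 correspondences")
    p_bar = p.mean(axis=0)
    q_bar = q.mean(axis=0)
    pc = p - p_bar
    qc = q - q_bar
    # degenerate (collinear) geometry: the rotation about the common line is
    # unobservable
    s = np.linalg.svd(pc, compute_uv=False)
    if s[1] < 1e-12 * max(1.0, s[0]):
        raise ValueError("degenerate correspondence geometry (collinear points)")
    H = pc.T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = q_bar - R @ p_bar
    return RigidTransform(R, t)


def icp(source: PointCloud, target: PointCloud, params: ICPParams | None = None) -> ICPResult:
    """Point-to-point ICP refining an already rough-aligned source onto target.

    Each iteration pairs every target point with its nearest source point
    within the gate, solves the rigid least-squares update, applies it, and
    evaluates the mean correspondence distance d of the updated pairs.
    ``converged`` is True iff the final d fell below ``d_threshold``;
    ``stalled`` marks termination on a vanishing change in d.
    """
    params = params or ICPParams()
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both clouds must be non-empty")
    cumulative = RigidTransform.identity()
    work = source.xyz.copy()
    tgt = target.xyz
    prev_d = np.inf
    d = np.inf
    n_pairs = 0
    best_d = np.inf
    best = (cumulative, np.inf, 0, 0)
    for it in range(1, params.max_iterations + 1):
        try:
            i, j, dist = find_correspondences(work, tgt, params.max_corr_dist)
        except ValueError:
            i = np.empty(0, int)
        ti, tj = i, j
        if len(i) >= 3 and params.trim_factor > 0:
            # estimate on trimmed pairs only: spurious pairs at the overlap
            # boundary otherwise bias the least-squares update
            cut = max(params.trim_factor * float(np.median(dist)), params.trim_floor)
            keep = dist <= cut
            if keep.sum() >= 3:
                ti, tj = i[keep], j[keep]
        if len(i) < 3:
            return ICPResult(cumulative, float(d if np.isfinite(d) else np.inf), it,
                             converged=False, n_pairs=int(len(i)),
                             message="no correspondences within gate")
        try:
            step = estimate_transform(ti, tj, work, tgt)
        except ValueError as exc:
            return ICPResult(cumulative, float(d if np.isfinite(d) else np.inf), it,
                             converged=False, n_pairs=int(len(i)), message=str(exc))
        work = step.apply(work)
        cumulative = step.compose(cumulative)
        # mean distance over the full gated correspondence set
        d = float(np.sqrt(((work[j] - tgt[i]) ** 2).sum(axis=1)).mean())
        n_pairs = int(len(i))
        if d < best_d:
            best_d = d
            best = (cumulative, d, it, n_pairs)
        if d < params.d_threshold:
            return ICPResult(cumulative, d, it, converged=True, n_pairs=n_pairs)
        if abs(prev_d - d) < params.stall_delta:
            return ICPResult(cumulative, d, it, converged=False, n_pairs=n_pairs,
                             stalled=True)
        if d > 2.0 * best_d + params.stall_delta:
            # diverging: report the best iterate seen
            cum, bd, bit, bn = best
            return ICPResult(cum, bd, it, converged=bd < params.d_threshold,
                             n_pairs=bn, message="diverged; best iterate returned")
        prev_d = d
    cum, bd, bit, bn = best
    return ICPResult(cum, bd, params.max_iterations, converged=False,
                     n_pairs=bn, stalled=False)


def _crop_near(cloud: PointCloud, box_lo: np.ndarray, box_hi: np.ndarray,
               margin: float) -> PointCloud:
    lo = box_lo - margin
    hi = box_hi + margin
    mask = np.all((cloud.xyz >= lo) & (cloud.xyz <= hi), axis=1)
    return cloud.subset(mask)


def merge_blocks(blocks: list[PointCloud], spacing: float = 1.90,
                 params: ICPParams | None = None, travel_axis: str = "z",
                 max_correction: float = 0.20,
                 max_correction_rot_deg: float = 10.0,
                 pre_align_gate: float = 0.0,
                 pre_align_stride: int = 7) -> MergeResult:
    """Coarse-align, ICP-refine, and append each block into one strip cloud.

    Block ``k`` (1-based) is initialized from the previous block's refined
    pose composed with the incremental stop offset (``spacing`` along the
    travel axis).  This odometry-style prior matters because the strip is
    anchored in the first block's frame: any tilt of block 1 displaces
    distant strip content proportionally to its distance, so a plain
    ``coarse_offset`` start would drift out of the ICP basin on long strips.

    Refinement is ICP against the part of the strip near the block's
    bounding box.  An optional wide-gate pre-alignment pass
    (``pre_align_gate`` > 0, on clouds subsampled by ``pre_align_stride``)
    can absorb decimeter-scale stop errors but is off by default — with the
    odometry prior the residual misalignment sits well inside the fine
    gate's basin.  The refined pose is
    used whenever ICP produced a stable, plausible estimate; on structural
    failure — no correspondences, degenerate geometry, or a correction
    larger than the stop-pose prior allows (``max_correction`` m /
    ``max_correction_rot_deg``) — the block falls back to its prior
    placement (logged).  Output point count is the sum of the block sizes.
    """
    if not blocks:
        raise ValueError("need at least one block")
    params = params or ICPParams()
    merged = blocks[0]
    transforms = [RigidTransform.identity()]
    icp_results: list[ICPResult | None] = [None]
    fallbacks: list[int] = []
    step = RigidTransform.translation(coarse_offset(2, spacing, travel_axis))
    for k in range(2, len(blocks) + 1):
        block = blocks[k - 1]
        init = transforms[k - 2].compose(step)
        shifted = block.transformed(init.R, init.t)
        lo = shifted.xyz.min(axis=0)
        hi = shifted.xyz.max(axis=0)
        local_target = _crop_near(merged, lo, hi,
                                  max(pre_align_gate, params.max_corr_dist))
        result: ICPResult | None = None
        total = init
        if len(local_target) >= 3:
            refine = RigidTransform.identity()
            if (pre_align_gate > 0 and pre_align_stride >= 1
                    and len(shifted) > 10 * pre_align_stride):
                pre_params = ICPParams(d_threshold=params.d_threshold,
                                       max_iterations=min(params.max_iterations, 15),
                                       max_corr_dist=pre_align_gate,
                                       trim_factor=params.trim_factor,
                                       trim_floor=max(params.trim_floor, 0.02))
                pre = icp(shifted.subset(np.arange(0, len(shifted), pre_align_stride)),
                          local_target.subset(np.arange(0, len(local_target),
                                                        pre_align_stride)),
                          pre_params)
                if pre.n_pairs >= 3 and np.isfinite(pre.final_d):
                    shifted = shifted.transformed(pre.transform.R, pre.transform.t)
                    refine = pre.transform
            result = icp(shifted, local_target, params)
            combined = result.transform.compose(refine)
            centroid = block.transformed(init.R, init.t).xyz.mean(axis=0)
            correction = np.linalg.norm(combined.apply(centroid) - centroid)
            accept = (result.n_pairs >= 3 and np.isfinite(result.final_d)
                      and correction <= max_correction
                      and np.degrees(combined.rotation_angle())
                      <= max_correction_rot_deg)
            if accept:
                shifted = shifted.transformed(result.transform.R, result.transform.t)
                total = combined.compose(init)
            else:
                shifted = block.transformed(init.R, init.t)
                fallbacks.append(k)
                log.warning("block %d: ICP failed (%s); prior placement kept",
                            k, result.message or "implausibly large correction")
        else:
            fallbacks.append(k)
            log.warning("block %d: no overlap with strip; prior placement kept", k)
        merged = PointCloud.concat([merged, shifted], source_tag="strip")
        transforms.append(total)
        icp_results.append(result)
    return MergeResult(merged, transforms, icp_results, fallbacks)
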