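"""End-to-end orchestration of the phenotyping data path.

Stage order: stitch each stop's frames into a block → coarse + ICP merge of
the blocks into a strip → statistical outlier removal → RANSAC ground
detection → horizontal calibration (ground normal to +z) → ground removal →
Euclidean/K-means plant segmentation → per-plant height and crown width →
trait CSV and a run report.  Fully deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cloudio
from .cloudio import FrameStream, PointCloud, TraitTable
from .groundplane import (PlaneModel, RansacParams, SORParams, calibrate_horizontal,
                          orient_plane, ransac_plane, sor_filter)
from .registration import ICPParams, MergeResult, RigidTransform, merge_blocks
from .segmentation import ClusterSet, EuclidParams, KMeansParams, segment_plants
from .stitching import RailConfig, stitch
from .traits import EvalReport, evaluate, max_crown_width, plant_height

__all__ = ["PipelineConfig", "RunReport", "PipelineResult", "run_pipeline",
           "run_from_streams", "evaluate_against_truth"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    rail: RailConfig = field(default_factory=lambda: RailConfig.from_speed("344 cm/min"))
    icp: ICPParams = field(default_factory=ICPParams)
    sor: SORParams = field(default_factory=SORParams)
    ransac: RansacParams = field(default_factory=RansacParams)
    euclid: EuclidParams = field(default_factory=EuclidParams)
    kmeans_base: KMeansParams = field(default_factory=KMeansParams)
    pot_height: float = 0.10
    expected_count: int | None = None
    spacing: float = 1.90
    seed: int = 0
    frames_path: str | None = None
    truth_path: str | None = None
    out_dir: str | None = None

    _SECTIONS = {"rail", "icp", "sor", "ransac", "euclid", "kmeans",
                 "pot_height", "expected_count", "spacing", "seed", "paths"}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - cls._SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def sect(name, allowed):
            sub = dict(data.get(name) or {})
            bad = set(sub) - set(allowed)
            if bad:
                raise ValueError(f"unknown keys in '{name}': {sorted(bad)}")
            return sub

        rail_kw = sect("rail", ("speed", "fps", "travel_axis", "direction"))
        rail = RailConfig.from_speed(rail_kw.pop("speed", "344 cm/min"),
                                     fps_f=float(rail_kw.pop("fps", 15)),
                                     **rail_kw)
        icp_kw = sect("icp", ("d_threshold", "max_iterations", "max_corr_dist",
                              "stall_delta"))
        sor_kw = sect("sor", ("k_neighbors", "std_ratio"))
        ransac_kw = sect("ransac", ("iterations", "distance_threshold", "refit"))
        euclid_kw = sect("euclid", ("radius", "min_cluster_size"))
        km_kw = sect("kmeans", ("max_iter", "init"))
        paths = sect("paths", ("frames", "truth", "out"))
        seed = int(data.get("seed", 0))
        return cls(
            rail=rail,
            icp=ICPParams(**icp_kw),
            sor=SORParams(**sor_kw),
            ransac=RansacParams(seed=seed, **ransac_kw),
            euclid=EuclidParams(**euclid_kw),
            kmeans_base=KMeansParams(seed=seed, **km_kw),
            pot_height=float(data.get("pot_height", 0.10)),
            expected_count=(None if data.get("expected_count") is None
                            else int(data["expected_count"])),
            spacing=float(data.get("spacing", 1.90)),
            seed=seed,
            frames_path=paths.get("frames"),
            truth_path=paths.get("truth"),
            out_dir=paths.get("out"),
        )

    @classmethod
    def for_strip(cls, seed: int, expected_count: int | None = None,
                  range_noise: float = 0.002) -> "PipelineConfig":
        """Analysis settings for dense multi-stop strip clouds.

        Differences from the bare operation defaults, chosen for the
        duplicate-heavy return pattern of a slow rail scan (each surface
        patch is swept by many frames): the SOR neighborhood and cutoff are
        relaxed to ``k = 12, mu + 2.5 sigma`` so sparse-but-valid canopy
        tops survive, and ICP runs to geometric stall rather than stopping
        at a mean-distance threshold that duplicate returns undercut.  With
        no range noise the outlier filter has nothing to remove and is
        effectively disabled.  Rationale in docs/methods.md.
        """
        sor = SORParams(12, 2.5) if range_noise > 0 else SORParams(20, 6.0)
        return cls(seed=seed, expected_count=expected_count, sor=sor,
                   icp=ICPParams(d_threshold=1e-4, max_iterations=60),
                   ransac=RansacParams(seed=seed),
                   kmeans_base=KMeansParams(seed=seed))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)       # name -> counts/timing
    block_transforms: list = field(default_factory=list)     # 4x4 lists
    calibration: list | None = None                  # 4x4 list
    plane: dict | None = None
    eval_height: dict | None = None
    eval_crown: dict | None = None
    invalid_plants: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages[name] = {"seconds": round(seconds, 3), **counts}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


@dataclass
class PipelineResult:
    traits: TraitTable
    report: RunReport
    merged: PointCloud | None = None
    calibrated: PointCloud | None = None
    clusters: ClusterSet | None = None
    plane: PlaneModel | None = None
    calibration: RigidTransform | None = None
    merge: MergeResult | None = None


def run_from_streams(streams: list[FrameStream], cfg: PipelineConfig,
                     keep_intermediates: bool = False) -> PipelineResult:
    """Run the full data path on in-memory frame streams (one per stop)."""
    report = RunReport()
    t0 = time.perf_counter()
    blocks = [stitch(s, cfg.rail) for s in streams]
    report.add_stage("stitch", time.perf_counter() - t0,
                     blocks=len(blocks),
                     points_per_block=[len(b) for b in blocks])

    t0 = time.perf_counter()
    merge = merge_blocks(blocks, spacing=cfg.spacing, params=cfg.icp,
                         travel_axis=cfg.rail.travel_axis)
    merged = merge.cloud
    assert len(merged) == sum(len(b) for b in blocks)
    report.block_transforms = [t.matrix().tolist() for t in merge.transforms]
    report.add_stage("register", time.perf_counter() - t0, points=len(merged),
                     fallbacks=merge.fallbacks)

    t0 = time.perf_counter()
    filtered, removed = sor_filter(merged, cfg.sor)
    report.add_stage("sor", time.perf_counter() - t0, kept=len(filtered),
                     removed=int(removed.sum()))

    t0 = time.perf_counter()
    plane = ransac_plane(filtered, cfg.ransac)
    off_plane = filtered.xyz[~plane.inlier_mask]
    plane = orient_plane(plane, off_plane if len(off_plane) else filtered.xyz)
    report.plane = {"A": plane.A, "B": plane.B, "C": plane.C, "D": plane.D,
                    "n_inliers": plane.n_inliers}
    report.add_stage("ransac", time.perf_counter() - t0, inliers=plane.n_inliers)

    t0 = time.perf_counter()
    calibrated, cal = calibrate_horizontal(filtered, plane)
    plane_cal = plane.transformed(cal)
    report.calibration = cal.matrix().tolist()
    nonground = calibrated.subset(~plane.inlier_mask)
    report.add_stage("calibrate", time.perf_counter() - t0,
                     nonground=len(nonground), ground=plane.n_inliers)

    t0 = time.perf_counter()
    travel = np.zeros(3)
    travel["xyz".index(cfg.rail.travel_axis)] = 1.0
    lateral = np.array([1.0, 0.0, 0.0])
    clusters = segment_plants(nonground, cfg.euclid, cfg.kmeans_base,
                              expected_count=cfg.expected_count,
                              order_axis=cal.R @ travel,
                              lateral_axis=cal.R @ lateral)
    report.add_stage("segment", time.perf_counter() - t0, clusters=len(clusters),
                     discarded_points=clusters.n_discarded)

    t0 = time.perf_counter()
    rows = []
    for i, label in enumerate(clusters.labels):
        pts = clusters.points(i)
        h = plant_height(pts, plane_cal, cfg.pot_height)
        c = max_crown_width(pts, plane_cal, cfg.pot_height, exclude_pot=True)
        if not (h.valid and c.valid):
            report.invalid_plants.append(label)
        cx, cy = pts.xyz[:, 0].mean(), pts.xyz[:, 1].mean()
        rows.append({"plant_id": label, "height_m": h.height,
                     "crown_width_m": c.width, "n_points": len(pts),
                     "cx": float(cx), "cy": float(cy)})
    traits = TraitTable.from_rows(rows)
    report.add_stage("traits", time.perf_counter() - t0, plants=len(traits))

    result = PipelineResult(traits, report, plane=plane_cal, calibration=cal)
    if keep_intermediates:
        result.merged = merged
        result.calibrated = calibrated
        result.clusters = clusters
        result.merge = merge
    return result


def _load_streams(frames_path: str) -> list[FrameStream]:
    path = Path(frames_path)
    if path.is_file():
        return [cloudio.read_frames(path)]
    entries = sorted([p for p in path.iterdir()
                      if p.stem.startswith("stop") and
                      (p.is_dir() or p.suffix.lower() == ".csv")])
    if not entries:
        raise FileNotFoundError(f"no stop_* frame archives under {path}")
    return [cloudio.read_frames(p) for p in entries]


def evaluate_against_truth(traits: TraitTable, truth_df,
                           truth_xy: np.ndarray | None = None
                           ) -> tuple[EvalReport, EvalReport]:
    """Pair estimated and true traits and compute R²/RMSE for both traits.

    With ``truth_xy`` — the true pot centers expressed in the same
    (calibrated strip) frame as the trait table's ``cx, cy`` — plants are
    paired by optimal assignment on centroid distance, independent of
    labeling order.  Without it, both tables must use the shared labeling
    convention (ascending travel-axis position) and are paired row by row.
    """
    if len(traits) != len(truth_df):
        raise ValueError(f"plant count mismatch: {len(traits)} estimated vs "
                         f"{len(truth_df)} true")
    est = traits.df
    if truth_xy is not None:
        from scipy.optimize import linear_sum_assignment
        e = est[["cx", "cy"]].to_numpy(float)
        cost = np.linalg.norm(e[:, None, :] - np.asarray(truth_xy)[None, :, :],
                              axis=2)
        ei, ti = linear_sum_assignment(cost)
        order = np.empty(len(est), dtype=int)
        order[ei] = ti
        truth_df = truth_df.iloc[order].reset_index(drop=True)
    h = evaluate(est["height_m"].to_numpy(), truth_df["true_height"].to_numpy())
    c = evaluate(est["crown_width_m"].to_numpy(),
                 truth_df["true_crown_width"].to_numpy())
    return h, c


def run_pipeline(cfg: PipelineConfig, keep_intermediates: bool = False) -> PipelineResult:
    """Load frame archives, run the data path, and write outputs.

    Writes ``traits.csv``, ``report.json``, ``strip.ply`` (binary), and
    ``plane.json`` under ``cfg.out_dir`` when set.  If a truth table is
    configured the agreement metrics are evaluated and included in the
    report.
    """
    if not cfg.frames_path:
        raise ValueError("config has no paths.frames")
    streams = _load_streams(cfg.frames_path)
    result = run_from_streams(streams, cfg, keep_intermediates=True)
    if cfg.truth_path:
        truth_df = pd.read_csv(cfg.truth_path)
        h, c = evaluate_against_truth(result.traits, truth_df)
        result.report.eval_height = h.as_dict()
        result.report.eval_crown = c.as_dict()
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cloudio.write_traits(result.traits, out / "traits.csv")
        result.report.to_json(out / "report.json")
        cloudio.write_cloud(result.calibrated, out / "strip.ply", "ply_binary")
        with open(out / "plane.json", "w") as fh:
            json.dump(result.report.plane, fh, indent=2)
    if not keep_intermediates:
        result.merged = result.calibrated = None
        result.clusters = result.merge = None
    return result
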