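"""Synthetic rail-borne multi-beam LiDAR scans of potted-plant strips.

The generator emulates the acquisition geometry of a 16-beam 360° scanner
(±15° fan at 2° steps, 15 frames/s) mounted 1 m above the ground on a slide
rail, with the scanner's spin axis along the travel direction, so the beam
fan spans ±15° *along* the rail and the azimuth sweep circles under the
sensor.  A strip of potted plants on a (possibly tilted, rough) ground plane
is scanned from discrete stops spaced 190 cm apart, with rail travel per
stop sized so adjacent block extents overlap by 30 %.

World frame: x = travel direction, y = across-row, z = up, ground near
z = 0.  Sensor/block frame (what the frame streams and stitched blocks are
in): x = world y, y = world z - mount height, z = world x relative to the
stop — i.e. the travel axis is sensor +z and the true vertical is sensor +y,
which horizontal calibration later rotates to +z.

Scene surface points are sampled once; a frame "sees" a sample if it lies
within range, and within a beam's footprint in elevation; one return (the
nearest) is kept per beam/azimuth bin.  There is no occlusion ray-casting —
multi-echo canopy penetration means interior canopy points are genuinely
sampleable for this sensor class.  Ground truth is recomputed from the
realized samples, so pipeline recovery error is measured against what the
scanner could actually have seen, not against generative parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloudio import Frame, FrameStream, PointCloud
from .registration import RigidTransform
from .stitching import RailConfig

__all__ = [
    "SensorConfig",
    "SceneConfig",
    "GroundTruthTable",
    "Scene",
    "generate_scene",
    "scan_scene",
    "make_blocks",
    "brute_force_xy_diameter",
]

log = logging.getLogger(__name__)


@dataclass
class SensorConfig:
    """16-beam scanner geometry.

    ``beam_half_width_deg`` is the effective beam footprint half-width used
    to decide whether a discrete beam direction hits a pre-sampled surface
    point (real multi-beam scanners have ~0.1–0.2° beam divergence).
    """

    n_beams: int = 16
    fov_deg: float = 15.0               # fan spans ±fov_deg
    beam_half_width_deg: float = 0.15
    azimuth_step_deg: float = 0.2       # horizontal resolution, 0.1–0.4
    fps: float = 15.0
    mount_height: float = 1.0           # m above ground
    max_range: float = 10.0             # m

    def __post_init__(self) -> None:
        if self.n_beams < 1 or self.azimuth_step_deg <= 0:
            raise ValueError("invalid sensor configuration")

    @property
    def beam_angles_deg(self) -> np.ndarray:
        """Beam elevations, ±fov at uniform steps (2° for the 16-beam unit)."""
        return np.linspace(-self.fov_deg, self.fov_deg, self.n_beams)

    @property
    def beam_step_deg(self) -> float:
        return 2 * self.fov_deg / (self.n_beams - 1) if self.n_beams > 1 else 1.0


@dataclass
class SceneConfig:
    """Potted-plant strip layout, plant archetype, and acquisition geometry.

    Defaults describe the emulated study conditions: 9 stops x 6 plants = 54
    potted lettuce in two rows, stops every 1.90 m with 30 % block overlap,
    2 mm range noise, and stop-pose errors up to (2°, 3 cm).
    """

    n_stops: int = 9
    plants_per_stop: int = 6
    n_rows: int = 2
    pot_spacing: float = 0.60           # along-row plant spacing (m)
    row_offset: float = 0.25            # rows at y = ±row_offset (m)
    pot_height: float = 0.10            # h_p (m)
    pot_radius: float = 0.075
    height_range: tuple = (0.10, 0.35)  # plant height h above pot rim (m)
    crown_range: tuple = (0.15, 0.40)   # maximum crown width L (m)
    leaves_per_plant: int = 10
    samples_per_leaf: int = 18
    stem_samples: int = 20
    pot_samples: int = 36
    ground_grid: float = 0.06           # ground sample spacing (m)
    ground_half_width: float = 0.7      # ground strip extends to y = ±this
    ground_tilt_deg: float = 0.5        # slope along x
    ground_roughness: float = 0.003     # sigma_g (m)
    range_noise: float = 0.002          # sigma along the line of sight (m)
    stop_spacing: float = 1.90
    overlap_fraction: float = 0.30
    stop_perturb: tuple = (2.0, 0.03)   # (max rotation deg, max translation m)
    touch_group_size: int = 0           # squeeze this many plants until crowns touch
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.n_stops < 1 or self.plants_per_stop < 1 or self.n_rows < 1:
            raise ValueError("invalid scene counts")
        for name in ("height_range", "crown_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}")

    @property
    def n_plants(self) -> int:
        return self.n_stops * self.plants_per_stop

    @property
    def field_length(self) -> float:
        """Along-travel extent of one block, sized for the overlap fraction."""
        return self.stop_spacing / (1.0 - self.overlap_fraction)

    def rail_travel(self, sensor: SensorConfig) -> float:
        """Rail travel per stop so the block extent (travel + beam-fan margin
        at ground range) equals ``field_length``."""
        margin = sensor.mount_height * math.tan(math.radians(sensor.fov_deg))
        return max(self.field_length - 2 * margin, 0.2)

    def stop_positions(self) -> np.ndarray:
        return np.arange(self.n_stops) * self.stop_spacing


@dataclass
class GroundTruthTable:
    """Per-plant truth (from realized samples) and per-block perturbations."""

    plants: pd.DataFrame    # plant_id, true_height, true_crown_width, cx, cy
    block_transforms: list[RigidTransform] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.plants)


@dataclass
class Scene:
    """Sampled scene surface in world coordinates with per-point labels.

    ``cloud.aux["label"]`` is -1 for ground, else the plant index;
    ``cloud.aux["canopy"]`` marks leaf-surface samples (the points that
    define true crown width and height).
    """

    cloud: PointCloud
    truth: GroundTruthTable
    config: SceneConfig

    def ground_z(self, x, y):
        """True (noise-free) ground elevation under the tilt model."""
        return np.tan(np.radians(self.config.ground_tilt_deg)) * np.asarray(x, float)


def truth_strip_xy(scene: Scene, truth: GroundTruthTable,
                   calibration: RigidTransform,
                   sensor: SensorConfig | None = None) -> np.ndarray:
    """True pot centers expressed in the calibrated strip frame, (n, 2).

    Chains the world→block-0 axis mapping, the block-0 stop-pose
    perturbation, and the pipeline's horizontal-calibration rotation, then
    drops the vertical coordinate.  Used to pair estimated plants with truth
    rows independent of labeling order.
    """
    sensor = sensor or SensorConfig()
    cfg = scene.config
    cx = truth.plants["cx"].to_numpy(float)
    cy = truth.plants["cy"].to_numpy(float)
    zc = scene.ground_z(cx, cy) + cfg.pot_height
    block0 = np.column_stack([cy, zc - sensor.mount_height, cx])  # stop 0 at x=0
    if truth.block_transforms:
        block0 = truth.block_transforms[0].apply(block0)
    strip = calibration.apply(block0)
    return strip[:, :2]


def brute_force_xy_diameter(xyz: np.ndarray) -> float:
    """O(n²) farthest-pair distance of the xy projection (truth oracle)."""
    xy = np.asarray(xyz)[:, :2]
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def _sample_plant(rng: np.random.Generator, cfg: SceneConfig,
                  target_h: float, target_c: float):
    """One plant in local coordinates (origin at pot center on the ground).

    Returns ``(xyz, canopy_mask)``.  The canopy is a rosette of ellipsoidal
    leaf clusters around a short stem, rescaled so the realized samples hit
    the target height (max z = h_p + h) and crown width exactly; pot and stem
    samples are added below/inside.
    """
    hp = cfg.pot_height
    # leaf-volume samples on random ellipsoids around the axis: a multi-echo
    # scanner samples canopy interiors, not just the outer surface.  Samples
    # are allocated proportional to leaf volume and plant size so the cloud
    # density is roughly uniform, as in a real scan.
    geom = []
    for _ in range(cfg.leaves_per_plant):
        phi = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.2, 0.8)
        zc = rng.uniform(0.3, 0.8)
        center = np.array([rho * np.cos(phi), rho * np.sin(phi), zc])
        semi = np.array([rng.uniform(0.2, 0.4), rng.uniform(0.2, 0.4),
                         rng.uniform(0.1, 0.25)])
        geom.append((center, semi))
    # canopy surface grows like c*(c+h); normalize to a mid-range plant
    size_factor = float(np.clip(target_c * (target_c + target_h) / 0.1375,
                                0.6, 2.5))
    total = max(cfg.leaves_per_plant * cfg.samples_per_leaf * size_factor,
                8 * cfg.leaves_per_plant)
    weights = np.array([s.prod() for _, s in geom])
    weights /= weights.sum()
    pts = []
    for (center, semi), w in zip(geom, weights):
        n_leaf = max(8, int(round(total * w)))
        u = rng.normal(size=(n_leaf, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u *= np.cbrt(rng.uniform(size=(n_leaf, 1)))
        pts.append(center + u * semi)
    # petiole spokes from the stem axis to each leaf keep the rosette connected
    for center, _ in geom:
        frac = np.linspace(0.1, 0.98, 8)[:, None]
        axis_pt = np.array([0.0, 0.0, center[2]])
        pts.append(axis_pt + frac * (center - axis_pt))
    canopy = np.concatenate(pts)
    canopy[:, :2] -= canopy[:, :2].mean(axis=0)
    # rescale: exact target crown width in xy, exact target height in z
    diam = brute_force_xy_diameter(canopy)
    if diam > 0:
        canopy[:, :2] *= target_c / diam
    zmin, zmax = canopy[:, 2].min(), canopy[:, 2].max()
    span = max(zmax - zmin, 1e-9)
    z0 = min(0.2 * target_h, 0.04)   # canopy underside sits just above the rim
    canopy[:, 2] = hp + z0 + (canopy[:, 2] - zmin) / span * (target_h - z0)
    # stem from rim to just below the canopy top, so every leaf's petiole
    # chain has an attachment point
    t = np.linspace(0.02, 0.95, cfg.stem_samples)
    stem = np.column_stack([rng.normal(0, 0.004, cfg.stem_samples),
                            rng.normal(0, 0.004, cfg.stem_samples),
                            hp + t * target_h])
    # pot: upper wall band (the base is hidden at grazing incidence), an
    # evenly spaced rim ring, and the soil disk at the rim — ring and soil
    # keep the pot connected to the stem at realistic clustering radii
    ang = rng.uniform(0, 2 * np.pi, cfg.pot_samples)
    zp = rng.uniform(0.55 * hp, hp, cfg.pot_samples)
    pot = np.column_stack([cfg.pot_radius * np.cos(ang),
                           cfg.pot_radius * np.sin(ang), zp])
    n_rim = max(12, cfg.pot_samples // 3)
    rim_ang = np.linspace(0, 2 * np.pi, n_rim, endpoint=False)
    rim = np.column_stack([cfg.pot_radius * np.cos(rim_ang),
                           cfg.pot_radius * np.sin(rim_ang),
                           np.full(n_rim, hp)])
    n_soil = max(cfg.pot_samples // 2, 12)
    sr = cfg.pot_radius * np.sqrt(rng.uniform(0, 1, n_soil))
    sa = rng.uniform(0, 2 * np.pi, n_soil)
    soil = np.column_stack([sr * np.cos(sa), sr * np.sin(sa),
                            np.full(n_soil, hp * 0.95)])
    xyz = np.concatenate([canopy, stem, pot, rim, soil])
    canopy_mask = np.zeros(len(xyz), dtype=np.int8)
    canopy_mask[: len(canopy)] = 1
    return xyz, canopy_mask


def generate_scene(cfg: SceneConfig, sensor: SensorConfig | None = None) -> Scene:
    """Sample the scene surface and compute its ground truth.

    Deterministic given ``cfg.seed``.  Plant ids ``plant_001`` ... are
    assigned in ascending (x, y) order of pot centers, matching the labeling
    convention of the segmentation stage.
    """
    sensor = sensor or SensorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    tilt = math.tan(math.radians(cfg.ground_tilt_deg))
    margin = sensor.mount_height * math.tan(math.radians(sensor.fov_deg))
    x_lo = -margin
    x_hi = (cfg.n_stops - 1) * cfg.stop_spacing + cfg.rail_travel(sensor) + margin

    # pot centers: columns along x, n_rows across
    ncols = math.ceil(cfg.n_plants / cfg.n_rows)
    x0 = 0.5 * (x_lo + x_hi) - 0.5 * (ncols - 1) * cfg.pot_spacing
    centers = []
    for col in range(ncols):
        for row in range(cfg.n_rows):
            if len(centers) < cfg.n_plants:
                y = (row - (cfg.n_rows - 1) / 2.0) * 2 * cfg.row_offset
                centers.append([x0 + col * cfg.pot_spacing, y])
    centers = np.array(centers)

    # draw targets and sample every plant in local coordinates first, so a
    # touch group can be spaced from its *realized* along-row extents
    target_h = rng.uniform(*cfg.height_range, cfg.n_plants)
    target_c = rng.uniform(*cfg.crown_range, cfg.n_plants)
    local = [_sample_plant(rng, cfg, target_h[i], target_c[i])
             for i in range(cfg.n_plants)]
    if cfg.touch_group_size >= 2:
        g = cfg.touch_group_size
        idx = [i for i in range(cfg.n_plants) if centers[i, 1] == centers[0, 1]][:g]
        if len(idx) < g:
            raise ValueError("touch_group_size exceeds plants in one row")

        def x_half_extent(i):
            xyz, cmask = local[i]
            leaf = xyz[cmask.astype(bool)]
            return 0.5 * float(leaf[:, 0].max() - leaf[:, 0].min())

        x = centers[idx[0], 0]
        for a, b in zip(idx, idx[1:]):
            gap = x_half_extent(a) + x_half_extent(b) - 0.01
            x += max(gap, 2.1 * cfg.pot_radius)
            centers[b, 0] = x

    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < (2 * cfg.pot_radius) ** 2:
        raise ValueError("pot layout overlaps beyond tolerance")

    parts, labels, canopy = [], [], []
    rows = []
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    for rank, i in enumerate(order):
        xyz, cmask = local[i]
        base_z = tilt * centers[i, 0]
        xyz = xyz + np.array([centers[i, 0], centers[i, 1], base_z])
        parts.append(xyz)
        labels.append(np.full(len(xyz), rank, dtype=np.int64))
        canopy.append(cmask)
        leaf = xyz[cmask.astype(bool)]
        rows.append({
            "plant_id": f"plant_{rank + 1:03d}",
            "true_height": float(leaf[:, 2].max()) - base_z - cfg.pot_height,
            "true_crown_width": brute_force_xy_diameter(leaf),
            "cx": float(centers[i, 0]),
            "cy": float(centers[i, 1]),
        })

    gx = np.arange(x_lo, x_hi + cfg.ground_grid / 2, cfg.ground_grid)
    gy = np.arange(-cfg.ground_half_width, cfg.ground_half_width + cfg.ground_grid / 2,
                   cfg.ground_grid)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    gxy = np.column_stack([GX.ravel(), GY.ravel()])
    # jitter within each cell: real scans sample the ground quasi-continuously,
    # and a perfect lattice would hand ICP spurious cell-shifted optima
    gxy = gxy + rng.uniform(-0.5, 0.5, gxy.shape) * cfg.ground_grid
    gz = tilt * gxy[:, 0]
    if cfg.ground_roughness > 0:
        gz = gz + rng.normal(0, cfg.ground_roughness, len(gxy))
    ground = np.column_stack([gxy, gz])
    parts.append(ground)
    labels.append(np.full(len(ground), -1, dtype=np.int64))
    canopy.append(np.zeros(len(ground), dtype=np.int8))

    xyz = np.concatenate(parts)
    cloud = PointCloud(xyz, source_tag="scene",
                       aux={"label": np.concatenate(labels),
                            "canopy": np.concatenate(canopy)})
    truth = GroundTruthTable(pd.DataFrame(rows))
    return Scene(cloud, truth, cfg)


def scan_scene(scene: Scene | PointCloud, sensor: SensorConfig, rail: RailConfig,
               stop_position: float, travel_length: float | None = None,
               range_noise: float = 0.0, noise_seed: int = 0,
               block_transform: RigidTransform | None = None) -> FrameStream:
    """Scan the scene from one stop, producing sensor-relative frames.

    For frame ``k`` the sensor origin sits at ``mount_height`` above
    ``stop_position`` displaced by ``k * a / f`` along the rail.  A scene
    sample is returned when it is within ``max_range`` and within a beam's
    elevation footprint; one return (the nearest) is kept per
    (beam, azimuth-bin).  Gaussian range noise is added along the line of
    sight.  With ``range_noise = 0`` the emitted coordinates are the exact
    sensor-relative positions of the visible samples, so stitching inverts
    the acquisition exactly.  ``block_transform`` applies a rigid stop-pose
    error to the whole block (expressed in the stitched block frame).
    """
    cloud = scene.cloud if isinstance(scene, Scene) else scene
    cfg = scene.config if isinstance(scene, Scene) else None
    if travel_length is None:
        if cfg is None:
            raise ValueError("travel_length required when not passing a Scene")
        travel_length = cfg.rail_travel(sensor)
    rng = np.random.default_rng(np.random.SeedSequence([noise_seed, 202]))
    step = rail.step
    n_frames = int(math.floor(travel_length / step + 1e-9)) + 1

    xw, yw, zw = cloud.xyz.T
    order = np.argsort(xw, kind="stable")
    xs = xw[order]
    ys = yw[order]
    vs = zw[order] - sensor.mount_height      # vertical offset from sensor
    rho = np.hypot(ys, vs)
    azim = np.degrees(np.arctan2(vs, ys))
    n_bins = max(1, int(round(360.0 / sensor.azimuth_step_deg)))
    az_bin = np.minimum(((azim + 180.0) / 360.0 * n_bins).astype(np.int64), n_bins - 1)
    intens = cloud.intensity[order]
    scene_index = (cloud.aux.get("scene_index",
                                 np.arange(len(cloud), dtype=np.int64)))[order]

    beams = sensor.beam_angles_deg
    bstep = sensor.beam_step_deg
    hw = sensor.beam_half_width_deg
    fov_eff = sensor.fov_deg + hw
    max_dx = math.tan(math.radians(fov_eff)) * max(float(rho.max(initial=0.0)), 1e-6)

    frames = []
    total = 0
    for k in range(n_frames):
        sx = stop_position + rail.direction * k * step
        lo = np.searchsorted(xs, sx - max_dx)
        hi = np.searchsorted(xs, sx + max_dx)
        if hi <= lo:
            frames.append(Frame(k, PointCloud(np.empty((0, 3)),
                                              aux={"scene_index": np.empty(0, np.int64)})))
            continue
        dx = xs[lo:hi] - sx
        p_rho = rho[lo:hi]
        elev = np.degrees(np.arctan2(dx, p_rho))
        nearest = np.clip(np.round((elev + sensor.fov_deg) / bstep), 0,
                          sensor.n_beams - 1).astype(np.int64)
        hit = (np.abs(elev - beams[nearest]) <= hw) & (np.abs(elev) <= fov_eff)
        rng_dist = np.hypot(dx, p_rho)
        hit &= rng_dist <= sensor.max_range
        hit &= p_rho > 1e-9
        idx = np.flatnonzero(hit)
        if idx.size:
            key = nearest[idx] * n_bins + az_bin[lo:hi][idx]
            by_range = idx[np.argsort(rng_dist[idx], kind="stable")]
            key_sorted = nearest[by_range] * n_bins + az_bin[lo:hi][by_range]
            _, first = np.unique(key_sorted, return_index=True)
            idx = np.sort(by_range[first])
        sel = lo + idx
        # sensor-relative coordinates: x_s = y_w, y_s = z_w - mount, z_s = dx
        rel = np.column_stack([ys[sel], vs[sel], dx[idx]])
        if range_noise > 0 and len(rel):
            r = np.linalg.norm(rel, axis=1)
            rel = rel * (1.0 + rng.normal(0, range_noise, len(rel)) / r)[:, None]
        if block_transform is not None and len(rel):
            d = np.array([0.0, 0.0, rail.direction * k * step])
            rel = (rel + d) @ block_transform.R.T + block_transform.t - d
        total += len(rel)
        frames.append(Frame(k, PointCloud(rel, intens[sel],
                                          aux={"scene_index": scene_index[sel]})))
    if total == 0:
        log.warning("scan_scene: no visible points at stop %.3f", stop_position)
    return FrameStream(frames, rail_meta=rail)


def make_blocks(scene: Scene, sensor: SensorConfig | None = None,
                rail: RailConfig | None = None):
    """Scan every stop, applying a random rigid stop-pose error to each block.

    Returns ``(streams, truth)`` where ``truth.block_transforms[k]`` is the
    perturbation applied to block ``k`` (in its stitched block frame).
    Deterministic given the scene seed.
    """
    cfg = scene.config
    sensor = sensor or SensorConfig()
    rail = rail or RailConfig.from_speed("344 cm/min")
    travel = cfg.rail_travel(sensor)
    max_rot, max_trans = cfg.stop_perturb
    streams = []
    transforms = []
    pivot = np.array([0.0, -sensor.mount_height / 2.0, travel / 2.0])
    for k, stop in enumerate(cfg.stop_positions()):
        prng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303, k]))
        if max_rot > 0 or max_trans > 0:
            axis = prng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = math.radians(prng.uniform(0, max_rot))
            K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
            delta = prng.normal(size=3)
            delta = delta / np.linalg.norm(delta) * prng.uniform(0, max_trans)
            t = pivot - R @ pivot + delta
            transform = RigidTransform(R, t)
        else:
            transform = RigidTransform.identity()
        streams.append(scan_scene(scene, sensor, rail, float(stop), travel,
                                  range_noise=cfg.range_noise,
                                  noise_seed=cfg.seed * 1000 + k,
                                  block_transform=transform))
        transforms.append(transform)
    truth = GroundTruthTable(scene.truth.plants.copy(), transforms)
    return streams, truth
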