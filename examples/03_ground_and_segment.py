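"""Denoise, find the ground, calibrate to horizontal, and split single plants.

Statistical outlier removal discards sparse error points; RANSAC fits the
ground plane Ax+By+Cz+D=0 from random point triples scored by inlier count;
horizontal calibration rotates the fitted normal onto +z so heights can be
read off the z axis; Euclidean clustering then groups the remaining points
into one cluster per plant.
"""

import numpy as np

import railphen as rp

cfg = rp.SceneConfig(n_stops=2, plants_per_stop=3, n_rows=1, seed=9,
                     ground_tilt_deg=1.0)
scene = rp.generate_scene(cfg)
streams, truth = rp.make_blocks(scene)
rail = rp.RailConfig.from_speed("344 cm/min")
strip = rp.merge_blocks([rp.stitch(s, rail) for s in streams]).cloud

filtered, removed = rp.sor_filter(strip, rp.SORParams(k_neighbors=20, std_ratio=2.5))
print(f"SOR: removed {removed.sum()} of {len(strip)} points")

plane = rp.ransac_plane(filtered, rp.RansacParams(1000, 0.01, seed=9))
plane = rp.orient_plane(plane, filtered.xyz[~plane.inlier_mask])
print(f"ground plane: {plane.n_inliers} inliers, normal "
      f"({plane.A:+.3f}, {plane.B:+.3f}, {plane.C:+.3f}) in the raw sensor frame")

calibrated, cal = rp.calibrate_horizontal(filtered, plane)
print(f"after calibration the ground normal is {np.round(cal.R @ plane.normal, 6)}")

nonground = calibrated.subset(~plane.inlier_mask)
clusters = rp.segment_plants(nonground, rp.EuclidParams(0.05, 100),
                             order_axis=cal.R @ np.array([0.0, 0.0, 1.0]))
print(f"{len(clusters)} plants segmented (true count {len(truth.plants)}); "
      f"sizes {clusters.sizes.tolist()}")
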