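"""Full pipeline to per-plant traits, evaluated against simulator truth.

Plant height is h = Z_max - Z_min - h_p (highest crop point minus ground
elevation under the plant minus the known pot height).  Maximum crown width
is the rotating-calipers diameter of the convex hull of the plant's
pot-free xy projection.  Agreement is reported as the R² of a linear fit
and the RMSE of paired differences — the same metrics used to score the
platform against manual measurements.
"""

import railphen as rp
from railphen.simulate import truth_strip_xy

cfg = rp.SceneConfig(n_stops=3, plants_per_stop=6, seed=2)   # 18 plants
scene = rp.generate_scene(cfg)
streams, truth = rp.make_blocks(scene)

pipe = rp.PipelineConfig.for_strip(seed=2, expected_count=cfg.n_plants)
result = rp.run_from_streams(streams, pipe)
print(result.traits.df.head(6).to_string(index=False))

txy = truth_strip_xy(scene, truth, result.calibration)
height, crown = rp.evaluate_against_truth(result.traits, truth.plants, txy)
print(f"\nheight: R² = {height.r_squared:.4f}, RMSE = {height.rmse * 100:.2f} cm "
      f"(slope {height.slope:.3f}, intercept {height.intercept * 100:.2f} cm)")
print(f"crown:  R² = {crown.r_squared:.4f}, RMSE = {crown.rmse * 100:.2f} cm")
print("\nR² close to 1 and RMSE of a few millimeters mean the pipeline recovers "
      "the traits the scanner could see; residuals come from range noise, "
      "registration error, and the literal-maximum height rule.")
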