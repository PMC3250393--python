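"""Derive lidar habitat metrics from both lidar observation types.

Discrete-return lidar: point cloud -> DSM/DEM -> canopy height model ->
individual-tree detection -> stem density and crown-area-weighted height.
Waveform lidar: one 25 m footprint -> ground-corrected RH energy quantiles
and the canopy cover profile.
"""

from canopyfuse import drl, sensors, waveform
from canopyfuse.pipeline import calibration_window_model
from canopyfuse.scene import SceneConfig, build_scene

scene = build_scene(SceneConfig(extent=(300.0, 300.0), stem_density=400.0), seed=3)

cloud = sensors.simulate_drl(scene, density_per_m2=1.5, seed=4)
print(f"point cloud: {len(cloud)} returns from {cloud.pulse_id.nunique()} pulses")

extent = scene.terrain.extent
dsm = drl.interpolate_surface(cloud, "first", 0.5, extent)
dem = drl.interpolate_surface(cloud, "last", 0.5, extent)
chm = drl.compute_chm(dsm, dem)
print(f"CHM: max canopy height {chm.values.max():.1f} m")

window_model = calibration_window_model(scene, n_pairs=150, seed=3)
trees = drl.detect_trees(chm, window_model, min_height=2.0)
area = extent[0] * extent[1]
print(f"detected {len(trees)} dominant/co-dominant crowns "
      f"({drl.stem_density(trees, area):.0f} stems/ha; "
      f"true stand {len(scene.trees) / (area / 1e4):.0f} stems/ha incl. understory)")
print(f"crown-area-weighted height: {drl.crown_area_weighted_height(trees):.1f} m")

# one large-footprint waveform at the scene center, ground-corrected with
# the high-resolution DRL ground surface
wf = sensors.simulate_waveform(scene, (150.0, 150.0), seed=5)
ground = waveform.footprint_ground(dem, wf.center, wf.diameter)
corrected = waveform.ground_correct(wf, ground)
rh = waveform.rh_metrics(corrected)
prof = waveform.cover_profile(corrected)
print(f"\nwaveform footprint at (150, 150): ground {ground:.1f} m a.s.l.")
print(f"RH25/50/75/100 = {rh.rh25:.1f} / {rh.rh50:.1f} / {rh.rh75:.1f} / "
      f"{rh.rh100:.1f} m (heights of 25/50/75/100% cumulative energy)")
print(f"total canopy cover {prof.total_cover:.2f}; "
      f"5 m-bin profile {[round(float(b), 2) for b in prof.bin_cover]}")
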