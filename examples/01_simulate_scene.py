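"""Render a synthetic nanoarray AFM scene and save it with ground truth.

Builds a 6 x 6 um field of 200-nm tethering spots (pitch 400 nm), places
one vesicle on 20% of the spots plus a few lipoprotein-like particles at
spot rims, renders a noisy height map, and writes the scene to
scratch/example_scene/ (ASCII grid + layout/truth CSVs + JSON sidecar).
"""

from pathlib import Path

import evnanoarray as ev
import evnanoarray.io as evio

spec = ev.LayoutSpec(field_width_nm=6000, field_height_nm=6000,
                     pitch_nm=400, spot_diameter_nm=200)
cfg = ev.RenderConfig(pixel_size_nm=5, noise_sd_nm=0.3, tilt_x=0.001,
                      line_offset_sd_nm=0.2)
line = ev.CELL_LINES["Sk-Br-3"]

hmap, truth, layout = ev.simulate_scene(
    spec, cfg, occupancy=0.20, D_dist=line["D"], ar_dist=line["ar"],
    n_ldl=8, seed=1)

out = Path("scratch/example_scene")
out.mkdir(parents=True, exist_ok=True)
evio.write_height_map(hmap, out / "scene.asc")
evio.write_layout_csv(layout, out / "layout.csv")
evio.write_truth_csv(truth, out / "truth.csv")

evs = [p for p in truth.particles if p.klass == "EV"]
print(f"layout: {len(layout)} spots, density {layout.density_per_mm2:.3g} spots/mm^2")
print(f"rendered map: {hmap.shape[0]} x {hmap.shape[1]} px at {hmap.pixel_size_nm} nm/px")
print(f"particles: {len(evs)} EVs on spots, "
      f"{len(truth.particles) - len(evs)} lipoprotein-like at spot rims")
print(f"true occupancy: {truth.occupancy():.3f} "
      "(fraction of spots carrying a vesicle)")
print(f"files written to {out}/")
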