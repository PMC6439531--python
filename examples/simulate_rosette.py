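"""Render a short synthetic rosette series and compare truth to segmentation.

The simulator draws a multi-lobe rosette whose projected area grows
exponentially, sitting in a dark circular panel depression, and reports
exact per-frame truth alongside the rendered images.
"""

import numpy as np

import leafflow as lf

truth = lf.PlantTruth(center=(80, 60), initial_area=250, growth_rate=0.015,
                      nutation_amplitude=4)
cfg = lf.SimConfig(n_frames=13, capture_interval_min=60.0, image_size=(160, 120),
                   seed=1)
series = lf.simulate_rosette_series(truth, cfg)

print("frame  t(h)  true plant px  ExG-segmented px  detected center")
for k in (1, 7, 13):
    img = series.images[k - 1]
    seg = int(lf.exg_mask(img, 0.2).sum())
    cx, cy = lf.detect_center(img, cfg.depression_radius)
    print(f"{k:>5}  {cfg.time_of(k):>4.0f}  {series.plant_pixel_count(k):>13}"
          f"  {seg:>16}  ({cx:.0f}, {cy:.0f})")

ratio = series.plant_pixel_count(13) / series.plant_pixel_count(1)
print(f"\n12-h area ratio: {ratio:.2f} (exponential rule predicts "
      f"{np.exp(12 * truth.growth_rate):.2f})")
print("Segmented counts track the painted truth within a few percent, and the")
print("Hough-detected center sits on the simulated panel depression.")
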