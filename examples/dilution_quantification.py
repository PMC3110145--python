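"""Quantify a 2-fold serial dilution series and recover the decay slope.

Each dilution step halves the spot peak intensity, so the mean log2 spot
volume should fall on a line of slope -1 per step.
"""

import warnings

import omtgrid as og
from omtgrid.geometry import Rect
from omtgrid.quantify import dilution_analysis, measure_region

img, truth = og.generate_dilution(steps=8, fold=2.0, seed=1)
half = (truth.spec.spot_diameter_px + truth.spec.spot_gap_px) / 2.0

volumes: dict[int, list[float]] = {}
for (cr, cc), step in zip(truth.spot_centers, truth.dilution_step):
    region = Rect(int(cr - half + 0.5), int(cr + half + 0.5),
                  int(cc - half + 0.5), int(cc + half + 0.5))
    m = measure_region(img, region)   # Sobel edge -> fill -> morphology -> sum
    volumes.setdefault(int(step), []).append(float(m.volume))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = dilution_analysis(volumes)

print("dilution step -> mean log2 spot volume")
for step, mean in fit.as_series().items():
    print(f"  {step}: {mean:6.2f}")
print(f"fitted slope: {fit.slope:.3f}  (reference line: -1 per 2-fold step)")
print("A slope near -1 confirms the segmentation + volume measurement "
      "tracks true abundance across a 128-fold intensity range.")
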