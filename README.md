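# axoncaliber

Quantification of axon caliber and its dynamics from membrane-labeled
fluorescence time-lapse imaging, built for thin sensory axons (such as
zebrafish Rohon-Beard peripheral arbors) imaged in single
super-resolution confocal planes at ~5-minute intervals.

A membrane label (e.g. EGFP-CAAX) renders an axon as two bright boundary
lines with a dark lumen.  The package scores **caliber** at a location as
the distance between the two plasma-membrane intensity peaks on an
intensity profile taken perpendicular to the axon's center axis, and
builds every higher-level statistic on that primitive:

- **Branch architecture** — at a branch point, the primary segment P and
  its thicker/thinner daughters S1, S2 are each summarized by the mean of
  measurements 3, 4 and 5 μm from the branch point; symmetry = S2/S1
  (identically (S2/P)/(S1/P)), cross-sectional-area taper ratio
  (area_S1 + area_S2)/area_P = (S1/P)² + (S2/P)², and the radius scaling
  ratios S1/P and S2/P with their pooled population mean.
- **Caliber dynamics** — at fixed locations tracked across frames:
  sample SD (absolute dynamicity), %RSD = (SD / mean caliber) × 100
  (relative dynamicity), fold range, regressions of SD and %RSD on mean
  caliber, and a paired two-day comparison by permutation test.
- **Division geometry** — for axons crossing a dividing basal epithelial
  cell: region-grouped caliber comparison (dividing vs. neighbor cells,
  Mann-Whitney), round/flat frame selection as the consecutive pair with
  the largest border-to-border length increase, a paired round-vs-flat
  caliber comparison, pearling (SD of calibers at 1-μm increments), and a
  circular-arc model of the axon path over the rounded cell
  (R = (c² + 4h²)/(8h), arc = 2R·asin(c/2R) for chord c, sagitta h).
- **Statistics** — a paired permutation test (independent sign flips,
  exhaustive up to n = 20) and a Mann-Whitney rank-sum test (exact
  enumeration for small tie-free samples), implemented from first
  principles and validated against enumeration oracles.
- **Synthetic scenes** — a generator that renders membrane tubes, pearls,
  branches, scripted dynamics behaviors (traveling pearl, focal
  inflation/deflation, segment widening/narrowing, constriction point)
  and cell-division scenarios with exact ground truth, Airyscan-scale
  blur (0.14 μm FWHM, 0.04 μm pixels) and shot/read noise.

Centerlines are annotations (JSON schema below, or SWC import); the
package deliberately does no automatic tracing.

## Worked example

Simulate a branched axon, measure it, and summarize the branch point:

```
printf 'scene: {image_shape: [300, 420]}\n' > cfg.yaml
axoncaliber simulate --kind branched --seed 4 --config cfg.yaml --out demo
axoncaliber measure --images demo/scene.tif --centerline demo/centerline.json --out demo/m.csv
axoncaliber branches --measurements demo/m.csv --centerline demo/centerline.json --out demo/rep
```

`demo/rep_summary.json` then contains (true diameters 0.60/0.44/0.32 μm):

```
 "mean_P_um": 0.6012909999999999,
 "mean_S1_um": 0.4404866666666667,
 "mean_S2_um": 0.31880633333333336,
 "mean_symmetry": 0.7237593268052003,
 "mean_area_ratio": 0.8177714643550412,
 "pooled_scaling_ratio": 0.6313856352415055
```

i.e. the line scans recover the scripted calibers to a few nanometers,
and the derived statistics follow: the daughters' combined
cross-sectional area is 0.82 of the primary's (the arbor tapers in
area), the thinner daughter is 0.72 of the thicker one's caliber, and
the average daughter-to-primary radius ratio is 0.63.

The same workflow in Python:

```python
import numpy as np
from axoncaliber import *

scene = SceneConfig(seed=4, image_shape=(300, 420))
truth = make_branched_truth(scene)  # P/S1/S2 = 0.60/0.44/0.32 um
frame = ImageFrame(render_membrane_frame(truth, scene), pixel_size=scene.pixel_size)
cl = centerline_from_truth(truth)
ms = measure_along_segment(frame, cl, 1, [3.0, 4.0, 5.0], MeasurementConfig())
print([round(m.caliber, 3) for m in ms])   # [0.439, 0.44, 0.442]
```

## File formats

- Images: single-channel multi-frame TIFF (float32 photons).
- Centerline JSON: `{"segments": [{"id", "points": [[x_um, y_um], ...],
  "parent"}], "branch_points": [{"location", "parent", "children"}]}`.
- Measurement CSV: `frame_time_min, segment_id, arc_pos_um, caliber_um,
  flag_below_resolution, flag_single_peak, flag_ambiguous`, preceded by a
  `# config_hash=... seed=...` provenance line.
- Branch CSV: `P_um, S1_um, S2_um, symmetry, area_ratio, ratio_S1, ratio_S2`;
  dynamics CSV: `location_id, mean_um, sd_um, pct_rsd, n_valid, fold_range`.

All interfaces use micrometers; pixel coordinates never cross a module
boundary.  Every output embeds the seed and a configuration hash, and
deterministic paths are byte-identical across reruns.

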