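# curvmap

Analysis of **curvature-selective functional domains** in visual cortex from
intrinsic-signal optical imaging, together with a synthetic imaging simulator
that makes every stage testable against planted ground truth.

Intrinsic-signal imaging measures tiny stimulus-evoked reflectance changes
(~0.01–0.03 %) of cortex under red illumination; activation *darkens* the
image. In macaque V4, contrasting responses to drifting **curvature gratings**
(built by repeating an elliptical contour with long/short axis ratio a/b, the
*curvature index*) against straight gratings reveals sub-millimeter
(200–500 µm) *curvature domains*, organized by curvature degree and by the
orientation of the curve's apex, with spatial progressions from straight
toward highly curved representations. This package implements that entire
analysis chain:

- **stimuli** — curvature/straight gratings from the ellipse displacement
  field Δ(x) = a(1 − √(1 − x²/b²)), flashed curved lines, 64-block scrambled
  controls.
- **synth** — ground-truth cortical models (orientation maps with pinwheels,
  orientation/color bands, planted domains and progressions) and a forward
  imaging model: reflectance = R₀(1 − resp·k(t) + noise), k a gamma kernel
  peaking at 2.5 s.
- **preprocess** — dR/R = (F_x − F₀)/F₀; per-trial responses
  (R̄₈₋₁₆ − R̄₁₋₃)/R̄₁₋₃; pixel-wise paired t maps
  t_i = (R̄_i1 − R̄_i2)·√N / S_i; Gaussian high-pass + circular-mean
  low-frequency filtering.
- **domains** — p < 0.01 thresholding (two-tailed, activation sign),
  8-connected labeling, size = πR² morphometry (R = mean semi-axis of the
  second-moment ellipse), 0.2 mm exclusion, overlap percentages.
- **featuremaps** — orientation angle maps by vector averaging Σ r_θ e^{2iθ};
  pinwheel centers by plaquette winding of the doubled angle.
- **similarity** — ROI-restricted Pearson correlation matrices between
  condition maps; correlation vs. curvature-degree-difference regression.
- **progression** — nearest-domain chains from straight domains; centroid
  distance vs. curvature ratio.
- **timecourses** — domain-averaged dR/R traces; Wilcoxon rank-sum on frames
  9–18.

## Worked example

`examples/02_simulate_and_map.py` plants eight 0.2–0.5 mm curvature domains
at 0.02 % response amplitude, simulates 30 trials of each of 9 conditions
(4 curved orientations, 4 straight orientations, blank) at 4 Hz with 2
pre-stimulus frames, and computes the curved-vs-straight t map:

```
session: (9, 30, 20, 128, 128) (condition, trial, frame, row, col)
planted curvature domains: 8
mean t inside planted domains:  -7.39
mean t outside planted domains: +0.04
p<0.01 pixel fraction outside:  0.0107
Dice(significant pixels, planted mask) = 0.974
```

Preferred stimuli darken the image, so planted domains carry strongly
negative t; outside them the p < 0.01 rate sits at its nominal ~1 %, and the
significant-pixel mask reproduces the planted layout almost exactly
(Dice 0.97). `examples/03_detect_domains.py` then labels and measures the
domains (8/8 recovered, mean equivalent diameter 350 µm — inside the
200–500 µm range expected of V4 functional domains), and
`examples/04_similarity_matrix.py` shows the graded degree representation:

```
Spearman(correlation, degree difference) = -0.968
pooled regression slope = -0.172 per degree step (r² = 0.97)
```

The other examples cover stimulus geometry (01), straight→curved centroid
progressions with ~0.2 mm per-degree spacing (05), pinwheel detection with
zero net chirality (06), and domain timecourses with the frames 9–18
rank-sum comparison (07). Each runs in seconds and prints what its numbers
mean.

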