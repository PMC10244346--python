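# pscml

Image-based machine learning for controlling pluripotent-stem-cell (PSC)
differentiation from label-free bright-field microscopy.

Directed differentiation (PSC → cardiomyocyte, nephron progenitor, or
definitive endoderm) is notoriously variable: the outcome hinges on the
initial colony state and on getting the stage-I Wnt activation (CHIR99021
concentration x duration) right for each batch. This package implements the
analysis side of a live-cell imaging workflow that catches deviations
early, from bright-field images alone, for researchers running such
protocols or building screening pipelines on top of them:

* **Efficiency quantification** — the Differentiation Efficiency Index of a
  fluorescence image *I*: `(1/W²) Σ_{I_ij > α} I_ij` with α = 0.5, plus
  per-line normalization.
* **Early CHIR-dose assessment** — a 21-D handcrafted representation of
  0-12 h image streams (differential box-counting fractal dimension, local
  entropy, colony area / circumference / A-C ratio / brightness, dense
  optical flow; phase-pooled over pre/mid/post), a 3-class logistic dose
  classifier, and the per-concentration Deviation Score
  `(N_high − N_low)/N_c ∈ [−1, 1]` against the signed distance ΔCHIR from
  the batch's optimal range [c1, c2].
* **Initial colony-state scoring** — a 343-D morphological profile
  (texture, Hu moments, SIFT/ORB bag-of-keypoints, shape and
  centroid-contour-distance statistics, spacing) and a random-forest
  efficiency regressor.
* **Weakly supervised fate-region localization** — patch labeling from
  three-level annotation masks, a pluggable patch classifier with
  gradient-weighted class-activation mapping, whole-well reconstruction,
  segmentation metrics, and compound-screen ranking.
* **Bright-field → fluorescence translation** — a scaled-down conditional
  adversarial translator (U-Net-style generator, 16 px receptive-field
  patch discriminator, λ·L1 + cGAN objective).
* **Synthetic data** — a first-class generator of wells, streams, masks and
  batch tables with the statistical structure the models assume, so the
  entire package is testable without microscope data.

See `docs/methods.md` for the models, parameters and their rationale.

## Worked example

```python
import numpy as np
from pscml.synthetic_data import SyntheticPlan, generate_well, generate_stream
from pscml.efficiency import efficiency_index
from pscml.features_stream import stream_feature_vector

plan = SyntheticPlan(seed=0)

# a well at its line's optimal CHIR dose: fluorescence covers 25% of pixels
bright, fluor, mask = generate_well(plan, dose=6.0, seed=1)
res = efficiency_index(fluor)
print(f"efficiency index = {res.index:.3f}, positive fraction = {res.positive_fraction:.3f}")

# an overdosed 0-12 h stream: colonies contract, so the post-phase
# normalized area falls well below the pre-phase value
features = stream_feature_vector(generate_stream(plan, dose=10.0, seed=1)).as_dict()
print(f"normalized colony area, pre vs post phase: "
      f"{features['Area_pre']:.3f} -> {features['Area_post']:.3f}")
```

prints

```
efficiency index = 0.225, positive fraction = 0.250
normalized colony area, pre vs post phase: 0.957 -> 0.640
```

The positive fraction 0.250 is the generator's committed-area fraction at
the optimum; the index is slightly lower because it weights pixels by
intensity. The area drop 0.957 → 0.640 is the contraction signature the
dose classifier feeds on — an optimally dosed stream stays near 1.

A `psc` command line wraps the same functionality, e.g.
`psc simulate --seed 3 --n-wells 8 --out batch/`,
`psc io plan --wells 96 --grid 5 --z 3`, `psc dose label wells.csv
--duration 24`, `psc stream-features --dir streams/ --out features.csv`.

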