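# Methods

`pscml` implements an image-based machine-learning workflow for controlling
pluripotent-stem-cell (PSC) differentiation from label-free bright-field
microscopy. This note records the models, the parameters that matter, the
synthetic data the tests run on, and the numerical choices made where the
design was genuinely open.

## Efficiency quantification

The Differentiation Efficiency Index of a fluorescence image *I* with
intensities in [0, 1] is

    Index = (1 / n_pixels) * sum over pixels with I > alpha of I

with `alpha = 0.5`. Only pixels strictly above the threshold contribute, so
the index is monotone in every pixel intensity and non-increasing in alpha.
For images that are not square the normalizer is the pixel count. The
"fraction of reporter-positive cells" used in dose labeling is
operationalized as the fraction of pixels above alpha (`positive_fraction`);
whether a cytometric count would behave identically is unknowable from
images alone, so the proxy is explicit and configurable.

Because differentiation potential differs between cell lines even under
optimal induction, per-well efficiencies are normalized by the maximum
index within the same line before any cross-line model is fit.

## CHIR dose assessment from 0-12 h image streams

A stream is ten frames T1..T10 uniformly spanning 0-12 h after CHIR99021
addition. Seven features are computed:

* **Fractal dimension** — differential box counting. The image is an
  intensity surface; for box width *r* the plane is split into *r* x *r*
  cells and each cell needs `ceil(max/h) - ceil(min/h) + 1` boxes of height
  `h = r * 256 / side`. The canonical schedule is 16 widths `2 * k^i`,
  `k = 243^(1/15)` (geometric from 2 to 486); images smaller than 486 px
  use the same 16-step geometric construction ending at the image side.
  The grid uses `n = round(side / r)` cells per axis and the regression of
  log N against log(realized width) — regressing on the realized width
  `side / n` removes the quantization bias that nominal widths near the
  image side would otherwise introduce (a constant image then scores
  exactly 2, and estimates stay inside [2, 3] up to clipping at the
  boundary).
* **Local entropy / cell regions** — per-pixel Shannon entropy (base 2,
  256-bin histogram of 8-bit intensities) in a disc of radius 10; pixels
  with >= 3 bits count as cell-covered. Colony texture carries several
  bits; the cell-free well bottom, with about one gray level of sensor
  noise, stays near 2 bits. The colony profile (below) uses radius 5, as
  the two stages specify different neighborhoods.
* **Area, circumference, A/C ratio, brightness** of the cell regions
  (area as pixel fraction, circumference as total marching-squares contour
  length over the image side, brightness as mean interior intensity).
* **Optical flow** — a dense flow field between consecutive frames,
  estimated with the pyramidal iterative Lucas-Kanade solver from
  scikit-image (radius 8, i.e. a ~17 px integration window, 3 warps).
  Vectors with magnitude <= 4 px are discarded; the feature is the mean
  magnitude of the survivors, 0 if none survive. Planted rigid shifts in
  (4, 16] px are recovered within 15%.

Area, circumference, A/C ratio and flow sequences are divided by their
first value (sequences whose first value is below 1e-6 are left raw and
flagged). Frames pool into phases pre = T1-T3, mid = T4-T7, post = T8-T10
(flow pairs 1-3 / 4-6 / 7-9) by unweighted mean — contiguous near-thirds,
chosen here and configurable. The result is a 21-vector in fixed name order.

Dose classes are defined per batch and CHIR duration: concentrations whose
mean positive fraction reaches 20% span the optimal range [c1, c2]; the
signed distance dCHIR(c) is c - c1 below, 0 inside, c - c2 above. A
one-vs-rest multinomial logistic model with inverse-frequency class weights
maps stream features to {low, optimal, high}; regularization presets are
l1 with strength 1/4 (24 h) or 1/8 (36/48 h) on all 21 features, l2 with
strength 0.1 on the 4 ANOVA-selected features, and elastic net (l1 ratio
0.1, strength 0.05, SAGA solver) for leave-one-batch-out validation
(strength lambda maps to scikit-learn's C = 1/lambda). The Deviation Score
of concentration c pools its wells' predictions, (N_high - N_low) / N_c,
bounded in [-1, 1]; the printed formula's denominator is read as N_c since
only N_c is defined and the stated bounds require it. The optimal duration
is the one whose score is closest to 0 (ties to the shorter duration).

## Colony-state profiling (0 h)

343 features per whole-well image: 4 texture statistics of the cell regions
(local entropy at radius 5, brightness, contrast, total variation = mean
|gradient| L1 norm), the 7 Hu invariant moments of the raw grayscale image
(no log transform — raw values are kept and documented), a 256-D SIFT and a
64-D ORB bag-of-keypoints histogram, area / circumference / A-C ratio
(normalized by width squared and width), area-weighted per-component shape
statistics (solidity, convexity, circularity, and centroid-contour-distance
max / min / min-max ratio / mean / std over marching-squares contour
points), and the spacing (mean distance from the skeleton of the cell-free
space to the nearest cell pixel, averaged over skeleton pixels).
Components under 50 px are treated as specks and dropped (configurable).
Perimeters inside the shape statistics use the 4-direction Crofton
estimator, which is nearly unbiased on smooth shapes — a rasterized disc
scores circularity within a few percent of 1, where raw marching-squares
contour lengths overshoot by ~6%.

Codebooks are k-means (k = 256 SIFT / 64 ORB) fit on keypoints pooled from
images excluded from the modeling dataset; the fitting-image ids travel
with the codebook so disjointness can be enforced. The efficiency model is
a random forest: 1000 trees, depth 8, 15 features per split when ranking
feature importance; 20 trees for prediction; predictions clipped to [0, 1].

Descriptor families: SIFT descriptors are 128-D floats; ORB's 256 binary
tests are packed to the conventional 32-byte layout; the 64-D slot of the
448-D trajectory summary (per-dimension mean then population std of all
keypoints, family-major) is filled by BRIEF with 64 bits on Harris corners,
since SURF is patent-encumbered and not available in the installed stack —
the substitution is recorded in the summary's metadata. Detector
hyperparameters sit in one config block (`SIFT(upsampling=1, c_dog=0.02)`,
`ORB(n_keypoints=200, n_scales=3)`); they are choices of this package, not
assumed to match any other implementation's defaults.

## Weakly supervised localization

Whole-well images tile into patches (50% overlap for training, 75% at test
in the cardiac protocol; 25% for endoderm training — overlap is a
parameter). A patch is positive when >= 30% of its annotation is dark gray
(committed), negative when the annotation is all black, discarded
otherwise; light gray blocks the negative label but does not count toward
the 30%. The endoderm variant thresholds a binarized, morphologically
closed SOX17 mask at 20%. Grad-CAM on the classifier's last convolutional
activations A^k uses channel weights `alpha_k = (1/Z) sum_ij dy+/dA^k_ij`
(y+ the pre-softmax positive score) and `heatmap = ReLU(sum_k alpha_k A^k)`,
upsampled bilinearly to patch size. Negative-predicted patches get all-zero
maps. Maps are normalized to 0-255 per patch (zero maps stay zero),
binarized at 10, and reconstructed whole-well — heatmaps by mean, binaries
by logical OR (normalize-then-reconstruct follows the per-patch protocol
order; the alternative is selectable). Segmentation metrics follow the
standard confusion-matrix formulas, with dark gray and light gray counting
as ground-truth positives; images whose ground truth is all positive or all
negative are flagged discarded. Screens rank wells by predicted positive
fraction (top 40, candidate threshold 40%, ties by well id).

The backbone is a contract, not a class: anything exposing class
probabilities, last-conv activations, and their gradients works. The desk
backbone is a three-block CNN (8/16/16 channels, GAP, linear head) written
on this package's own numpy layer library (`pscml.nn`: im2col convolution,
instance norm, pooling, Adam, all with explicit backward passes verified
against finite differences); the full-scale configuration (ResNeSt-101,
300 epochs, batch 6, lr 3e-5, 20% validation split) is retained as a
preset for GPU-backed runs.

## Bright-field-to-fluorescence translation

The translator is a conditional-adversarial pair: an encoder-decoder
generator with skip connections, nearest-neighbor upsampling + convolution
(no transposed convolutions, avoiding checkerboard artifacts) and instance
normalization; and a patch discriminator whose score-map pixels have a
16 x 16 px receptive field, verified at build time by gradient probing.
The objective is `min_G max_D lambda * L1(G) + L_cGAN(G, D)` with
lambda = 100; the reported total decomposes exactly into the two terms.
The adversarial term is disabled after a configured epoch (half the run by
default) to favor reconstruction fidelity, freezing the discriminator.
Generator randomness is realized as dropout, off at inference (predictions
are deterministic). The full-scale preset (2000 epochs, 1260 patches of
256 px per epoch, batch 16, Adam beta1 = 0.5, lr 2e-4 with linear decay
over the second half) is configuration only; the tested desk preset uses
8 base channels, 64 px patches, 48 patches/epoch, 30 epochs, lr 4e-4.
Evaluation resizes prediction and truth to 512 px (256 px at desk scale),
reports the pixel-level Pearson r and a joint histogram with counts per 100.

## Synthetic data

The generator produces what the models assume, not photorealism:

* **Wells** — 5-8 colonies per 256 px well (elliptical, smoothed random
  boundary harmonics), band-limited noise texture inside colonies
  (sd 0.10), a darker domed base, an illumination gradient, and ~1 gray
  level of sensor noise outside (sd 0.004, deliberately below the 3-bit
  entropy criterion).
* **Dose response** — latent differentiation propensity is a Gaussian bump
  in log-concentration (sd 0.45 log units) centered on a line-specific
  optimum; the fate-committed area is the innermost colony pixels, counted
  so the committed fraction is exactly 0.25 x propensity (0.25 at the
  optimum, so the 20% labeling rule straddles three classes on a
  2-10 uM titration). Committed regions carry double-variance texture;
  fluorescence is bright (>0.5) only there, with noise added to the
  fluorescence, not the latent curve. Longer CHIR durations shift the
  effective optimum down (exponent 0.25), echoing the observed
  concentration-duration trade-off.
* **Streams** — colonies contract radially toward their centers with total
  0-12 h contraction 0.035 per uM (capped at 0.6) and brighten
  proportionally; the background field is frame-invariant so colony motion
  is the only apparent motion. A contraction override of 0 freezes the
  stream exactly.

All randomness flows through seeded generators derived from the plan seed;
identical plan + seed is byte-identical. What the generator does **not**
emulate: single-cell texture, autofocus drift, debris, uneven illumination
beyond a linear gradient, z-stacks, or biological heterogeneity beyond the
latent curve — so green tests demonstrate that the pipelines recover the
structure they assume, not that they will meet any particular accuracy on
real microscope data.

## Problem sizes used by the test suite

Parameter-recovery tests run at sizes chosen to exercise the full pipeline
on a single CPU: 200 wells/streams (3-class dose recovery; held-out
accuracy >= 0.90, deviation-vs-dCHIR Pearson r >= 0.8), 500 wells (colony
forest, held-out r >= 0.8), 8 training wells (weakly supervised
localization, IoU >= 0.5 on a held-out well), and 3 image pairs (desk
translator, pixel r >= 0.5 on a deterministic texture-to-fluorescence
mapping). Optical-flow magnitudes at this scale sit below the 4 px cutoff,
so the flow features are inert in the desk dose model — the contraction
signal is carried by area, circumference and brightness; the flow estimator
itself is validated on planted shifts.

## Known limitations

* The 64-D descriptor family is BRIEF, not SURF; summaries are not
  numerically comparable to OpenCV-based 448-D vectors.
* Dense flow is iterative Lucas-Kanade, not Farneback; both are dense and
  pyramidal, but magnitudes can differ near texture-poor regions.
* The numpy layer library is CPU-bound and desk-scale; the ResNeSt-101 and
  full pix2pix presets are configuration contracts for external backbones,
  not paths exercised here.
* `fractal_dimension` accepts images below 486 px by rescaling the box
  ladder; the canonical schedule applies only at full acquisition scale.
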