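# Methods

## The detection model

`stomadetect` treats stoma detection in leaf-impression micrographs as a
patch classification problem. A micrograph is divided into overlapping
120 × 120 px windows by a sliding window (default stride 30 px, a quarter
patch). A convolutional network scores each window with the probability
that a stoma is *fully visible* inside it; windows whose presence
confidence reaches the decision threshold τ (default 0.7) are kept, their
centers are clustered by flat-kernel mean shift (default bandwidth 60 px),
and each resulting mode becomes one detection: the mode coordinate, the
maximum member confidence, and the cluster size. Counts are converted to
stomatal density (stomata/mm²) through the microscope calibration — the
default field is 344 × 258 µm imaged at 1,600 × 1,200 px (0.0888 mm²,
0.215 µm/px).

The positive/negative labeling rule is geometric: a window is positive
iff at least one annotated stoma is fully contained in it, where the
stoma is approximated by the axis-aligned square of side `length_px`
centered at the annotated coordinates (annotations carry no orientation).
A stoma clipped by the window border — however slightly — makes that
window negative. This codifies the convention that only fully visible
stomata count, and it is exactly testable.

## Architectures and parameter accounting

Three architectures over 120 × 120 × 3 inputs are declared as data
(`architectures.py`) and instantiated by the NumPy backend:

| name | conv layers | dense head | params (total / trainable) |
|---|---|---|---|
| `basic_shallow` | 3×3 valid, depths 8–16–32, each + 2×2 max-pool | 32, 32, 2 | 180,242 / 180,242 |
| `basic_deep` | same topology, depths 32–64–128 | 1024, 1024, 2 | 23,297,090 / 23,297,090 |
| `vgg19` | standard 16-conv VGG19 base (3×3 same, 5 pool stages), frozen | 4096, 2048, 2 | 47,297,602 / 27,273,218 |

The parameter counter is pure integer arithmetic over the declared layer
chain (conv: 3·3·c_in·c_out + c_out; dense: (n_in+1)·n_out) and does not
touch the numeric backend, so these identities hold independently of any
training code. The valid-padding/2×2-pooling convention for the basic
nets (feature maps 120→118→59→57→28→26→13, flatten 13·13·32 = 5,408 for
the shallow net) and the 4096→2048→2 head on the 3×3×512 VGG19 output are
the unique conventions that reproduce all five totals exactly.

Per-architecture training defaults: Adam with α = 5e-4 / 5e-5 / 5e-6,
batch size 32 / 64 / 128 and 200 / 200 / 50 epochs for
shallow / deep / vgg19, β₁ = 0.9, β₂ = 0.999, dropout 0.5 on the dense
layers, and on-the-fly augmentation by random 90°-multiple rotations and
horizontal/vertical flips (restricted to the square's symmetry group so
no interpolation perturbs intensities and labels are trivially
preserved).

### Numerical choices

* **Backend.** Training and scoring run on a small seeded NumPy engine
  (float32, BLAS-backed im2col convolutions, exact argmax max-pool
  gradients, inverted dropout, softmax cross-entropy, Adam with bias
  correction). Analytic gradients are verified against central
  differences in the test suite. All randomness flows through explicit
  `numpy.random.Generator` streams, so a fixed seed reproduces
  initialization, batch order, dropout masks and the full loss history.
* **Input normalization.** Intensities are scaled to [0, 1] and centered
  by −0.5. Centering matters on these pale images: the near-constant
  background component otherwise dominates every feature map and the
  network settles into predicting the majority (negative) class.
* **Initialization.** He initialization for ReLU layers, smaller
  (1/√n_in) scale for the softmax layer.
* **VGG19 weights.** No pretrained convolutional weights ship with the
  package; building the vgg19 variant uses random frozen initialization
  and warns. The frozen base still participates in parameter accounting
  (20,024,384 frozen parameters) and in the forward pass.

## Mean-shift clustering

The basic flat-kernel formulation: each point moves to the mean of all
points within the bandwidth until its displacement falls below 1e-3 px
(at most 300 iterations); converged positions closer than bandwidth/2 are
merged into one mode, and every input point is assigned to its nearest
mode. The flat kernel was chosen over a Gaussian because its fixed points
are exactly checkable against a naive reference implementation (which the
package carries in `validation.py` and the tests exercise on hundreds of
random instances); a Gaussian kernel is available behind a flag. The
cluster coordinate reported is the mode itself — the density peak — not
the member centroid; cluster confidence is the maximum member score
(mean available behind a flag).

## Evaluation

Matching of detections to ground truth is one-to-one within a 60 px
radius (half a patch): greedy by ascending pairwise distance by default,
optimal (Hungarian) assignment behind a flag. The matching rule is this
package's construction — published detection scores in this domain
typically leave it implicit. TP/FP/FN feed precision, recall and the
F-score; threshold sweeps reuse one score map per image across the
19-point τ grid (0.05…0.95 in steps of 0.05), micro-averaged by default
(pooled counts; macro averaging optional). Per-image count accuracy uses
the deviation form 100·(1 − |computed − manual| / manual), floored at 0 —
the only reading under which a 36% count deviation corresponds to 64%
accuracy — and the counts relationship is summarized by OLS of computed
on manual counts with R² = 1 − SSres/SStot.

## The synthetic micrograph generator

The generator emulates focus-stacked brightfield images of nail-polish
epidermal impressions: a pale background composed of low-frequency
illumination mottle and mid-frequency cell texture; stomata as oriented
ellipses with a dark pore slit along the major axis, a lighter guard-cell
rim, and a faint boundary outline; artifacts (dark hair streaks, bright
bubbles with dark rings, dark smudges) placed away from stomata so labels
stay unambiguous; optional Gaussian blur; pixel noise; 8-bit
quantization. Defaults are the study conditions: 1,600 × 1,200 px frames,
25 stomata per frame, major axes 60–120 px (the size band a 120-px patch
handles), aspect ratio 0.4–0.8, minimum center separation 140 px (which
guarantees any 120-px window contains at most one complete stoma),
expected 3 artifacts per frame, noise σ = 0.03, blur σ = 1 px. Placement
is rejection sampling; infeasible packings raise an error naming the
achievable count. All randomness comes from NumPy's PCG64 generator, so
a fixed seed reproduces images and annotations byte-for-byte; dataset
generation derives per-image seeds from the master seed via a
`SeedSequence`.

What the generator does **not** model: species-specific guard-cell
morphology (kidney- vs dumbbell-shaped), uneven focus, staining
variation, dense or touching stomata, and hairy/velvety surfaces where
impressions fail. Passing tests on synthetic scenes therefore validate
the *machinery* — labeling geometry, training dynamics, clustering,
metrics — not performance on real herbarium imagery.

### The easy regime

With patch size P and stride s, the window origins that fully contain a
stoma of length L span an interval of length P − L per axis, so a
containing window is guaranteed only when L ≤ P − s (90 px at the
defaults); near the image border the truncated window grid can also cut
that interval off. `SynthConfig.easy()` therefore restricts major axes to
60–90 px and keeps centers one patch size away from the border. In this
regime an ideal window scorer provably yields exactly one cluster per
stoma, which is what the oracle-detector experiment asserts; the
end-to-end learning study uses the same regime so that its F-score
ceiling is 1. The generator default keeps the full 60–120 px band, where
the largest stomata may own no fully containing window at stride 30 —
mirroring the practical advice to adjust magnification when stomata
approach the patch size.

## Desk-scale experiment sizes

The reference experiments (`validation.py`, also used by
`scripts/acceptance.py`) are sized for a single CPU: 5 training scenes of
25 stomata yield ≈ 2,000 labeled patches at the default 6:1
negative:positive subsampling; the shallow net trains for 30 epochs with
its standard Adam settings; evaluation uses 6 held-out scenes across the
19-point τ grid. A representative run reaches training accuracy ≈ 0.96
and micro-averaged F ≈ 0.95 at τ = 0.7 on the held-out scenes. The
mean-shift reference comparison uses 200 random instances of ≤ 12 points
at bandwidths 30/60/120 px; the oracle-detector experiment uses 10
full-size scenes.

## Known limitations

* The training backend is CPU-bound NumPy; it is meant for desk-scale
  experiments and tests, not for training on hundreds of real
  micrographs (the vgg19 variant in particular is impractical to train
  here, though it builds, scores, and counts parameters correctly).
* Greedy matching is not guaranteed maximum-cardinality on adversarial
  geometries (the Hungarian option is); on well-separated detections the
  two agree.
* The count-accuracy convention is undefined for images with zero manual
  count; such images are skipped with a warning.
* Mean-shift cluster sizes depend on the stride: at finer strides a
  stoma attracts more windows, so `min_cluster_size` filtering is only
  meaningful relative to a fixed stride.
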