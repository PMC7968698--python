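# Methods

## Problem

Microfluidic aging chips hold single budding-yeast mother cells in
hundreds of small traps — pockets with a ~6 µm inlet at the top and a
~3 µm outlet at the bottom, so the medium flow washes newborn daughters
out while the mother stays put. Scoring replicative lifespan from the
resulting time-lapse images requires classifying, frame by frame and trap
by trap, what each 60×60-pixel trap sub-image shows. `trapnet` implements
and compares three image classifiers for that task and every surrounding
stage (synthetic data, partitioning, augmentation, metrics, ensembling).

## Category scheme

Classifiers are trained on five *computed* categories chosen for visual
homogeneity: `nC` (empty trap), `mC` (mother only), `mduC` (mother +
daughter above), `mddC` (mother + daughter below), `exC` (more than two
cells). `mduC` and `mddC` describe the same biological situation — a
mother with one daughter — so all reporting merges them into `mdC`,
giving four *biological* categories. Splitting by orientation during
training gives each class a consistent spatial pattern; merging afterwards
can only convert within-pair confusions into correct calls, so 4-category
accuracy is provably ≥ 5-category accuracy (`trapnet.labels` asserts and
tests this). Canonical orders are fixed as (`nC, mC, mduC, mddC, exC`) and
(`nC, mC, mdC, exC`); argmax ties break by canonical order.

## Architectures

All three models map a 60×60 single-channel tile with intensities in
[0, 1] to a probability vector over the five computed categories.

* **CNN-2** — two 3×3 convolutions (strides 1 and 2), batch normalization
  and ReLU on both, 2×2 max pooling, 25% dropout on the second layer, one
  hidden dense layer, softmax head. Trained with categorical
  cross-entropy.
* **CNN-13** — thirteen 3×3 convolutions in homogeneous groups
  (SimpleNet-style widths scaled to the 60×60 input), 2×2 pooling between
  groups, batch normalization and per-layer dropout, a single dense
  softmax head. Trained with categorical cross-entropy.
* **CapsNet** — a 9×9 stride-1 valid convolution (60 → 52), a 9×9
  stride-2 valid primary-capsule convolution (52 → 22) reshaped to a
  22×22 grid of 32 capsule types of dimension 8 (15,488 primary capsules),
  squashed with v = (|s|²/(1+|s|²))·s/|s|, and routed into five
  16-dimensional class capsules by dynamic routing: couplings are a
  softmax over zero-initialized logits, parent inputs are the
  coupling-weighted sums of the affine predictions û(j|i) = W(i,j)·u(i),
  and logits grow by the dot-product agreement û·v on all but the final
  iteration. Class probabilities are the squashed capsule lengths
  normalized to sum to one (length-proportional, not a softmax of
  lengths). Training minimizes the margin loss (m⁺ = 0.9, m⁻ = 0.1,
  λ = 0.5) plus a reconstruction error from a dense decoder fed the
  correct class capsule, down-weighted by 0.0005 per pixel sum-of-squares.

The capsule primitives also exist as standalone, fully vectorized NumPy
functions (`trapnet.capsule`), tested against brute-force loop oracles to
1e−10; the network layer is tested to agree with them.

## Training engine

No GPU framework is used: the networks run on `trapnet.nnet`, a compact
reverse-mode automatic-differentiation engine over NumPy arrays (tape of
operations, broadcasting-aware gradients, im2col convolution, fused
batch-norm backward, a two-operand einsum for the routing contractions).
Arithmetic is float32; everything is driven by `numpy.random.Generator`
streams derived from the run seed, so training histories are bit-for-bit
reproducible on a fixed NumPy build.

Choices that matter for small-sample stability, all defaults and all
overridable:

* Adam (lr per architecture, see below), global gradient-norm clipping at
  5, and a first-epoch warmup at a fifth of the target rate.
* Label smoothing 0.1 in the CNN cross-entropy. Hard scenes carry
  genuinely ambiguous labels (a near-transparent daughter is
  indistinguishable from no daughter); one-hot targets then push logits
  toward saturation, and a saturated-but-wrong member also poisons any
  probability-averaging ensemble it joins. Smoothing keeps the optimum at
  finite logits and the output probabilities calibrated.
* After every epoch, batch-norm running averages are replaced by exact
  population statistics of the training set under the current weights
  (dropout disabled for that pass). Stale exponential averages otherwise
  compound across a 13-layer stack and can collapse evaluation-mode
  predictions while training-mode accuracy climbs.
* The epoch whose weights score best on the validation split is kept
  (selection never touches the test split).
* He-normal initialization; capsule prediction weights N(0, 0.1).

## Synthetic scenes

The generator (`trapnet.synthetic`) renders what the classifier actually
faces: a trap outline converging from a 36 px inlet to an 18 px outlet
(6 px/µm, so the trap spans the central ~2/3 of the tile), cells as
anti-aliased ellipses with dark rims and lighter interiors (bright-field
appearance), and the label-defining configuration — no cells, a central
mother (radius 7–9 px easy mode), a daughter (3.5–5 px) strictly above or
below, or a mother plus 2–4 extra cells. Nuisance structure mimics the
failure modes reported for real chips: Gaussian blur (σ 0.4–0.8 px),
background level drawn from 0.55–0.70, one-sided multiplicative shadows
(probability 0.2), additive noise (σ 0.02), and occasional
near-transparent cells (2%).

**Hard mode** exists because a comparison needs imperfect classifiers: it
shrinks the mother/daughter separation to near-touching (offset factor
1.05), raises blur to σ 0.7–1.3, noise to 0.05, shadows to 40% and
transparent cells to 10% — calibrated so that every architecture lands
clearly below ceiling yet clearly above chance, which is the regime where
with/without-augmentation and single-vs-ensemble comparisons carry
information. Cell interiors are always placed with a ≥2 px gap so the
pre-noise ground-truth masks (kept on the dataset) have exactly one
connected component per cell; label and orientation faithfulness are
tested against a brute-force flood-fill oracle.

What the generator does **not** emulate: real trap-wall texture and
deformation, focus drift over a time series, cell-shape irregularity
beyond ellipses, debris, and the actual illumination field of any
particular microscope. Passing tests on synthetic scenes therefore
demonstrate that the pipeline's machinery is correct and that the
qualitative orderings hold under controlled difficulty — not that the
reported accuracies transfer to any real chip.

## Augmentation

Training-split-only, seeded, multiplier-controlled: rotation (±8°),
width/height shifts (±5% of the tile, edge-replicated borders),
brightness scaling (0.9–1.1×), horizontal flips, additive Gaussian noise
(σ 0.01), and optional feature-wise centering/std-normalization fitted on
the training split. The magnitudes are deliberately gentle: cells occupy
only ~8–18 px of the tile, and on already-degraded scenes stronger
transforms (±15°, ±10% shifts, ±20% brightness) shift the training
distribution so far that the smallest architecture scores *worse* with
augmentation than without, defeating the comparison the augmentation arm
exists for. Vertical flips are implemented but **off by
default**: flipping vertically moves a daughter from above to below the
mother, which silently relabels `mduC` as `mddC` — enabling it corrupted
5-space training measurably. Validation and test images are never
augmented.

## Metrics

Per-category metrics are one-vs-rest on the confusion matrix: accuracy
(TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN),
F1 = 2PR/(P+R). The TN term only has meaning in the one-vs-rest reading,
which is why that form is used for per-class accuracy; overall accuracy
is trace/total. Zero-denominator ratios report 0 and are flagged rather
than raised so batch evaluation always completes.

## Ensembles

From three fitted models there are exactly four ensembles (three pairs
plus the triple). Weights are the members' validation accuracies
normalized to sum to one (renormalized per membership), and predictions
are the convex combination of member probability vectors — a valid
probability vector by construction, invariant to member order, and equal
to any single member when the weights degenerate.

## Problem sizes and default hyperparameters

The standard benchmark (`trapnet.experiment.smoke_benchmark`, also what
`scripts/acceptance.py` runs) uses 100 scenes per category
(60/20/20 train/val/test), 5 epochs, augmentation multiplier 4, and
compact architecture widths chosen so the whole comparison — six
trainings plus four ensembles on hard mode, three trainings on easy
mode — completes in minutes on one CPU core: CNN-2 with 16/32 channels
and a 64-unit hidden layer; CNN-13 with widths 8×4, 16×4, 32×5 and
dropout scaled to 10% (25% per layer starves 8–32-channel feature maps
within a 5-epoch budget; the full-width `build_cnn13()` default keeps
25%); CapsNet with a 16-channel first convolution, 4 primary capsule
types and a (64, 128) decoder. Learning rates and batch sizes are per
architecture (CNN-2 1e−3/16, CNN-13 3e−3/16, CapsNet 1e−3/32), standing
in for what the 108-point hyperparameter grid search would select; the
epoch and data budget is shared across architectures so comparisons stay
like-for-like. Full-scale specs (`build_cnn2()`, `build_cnn13()`,
`build_capsnet()` with 256 conv channels and 32 capsule types) drop into
the same harness unchanged for larger runs.

## Known limitations

* The synthetic difficulty axis is one-dimensional (easy/hard presets);
  real datasets mix difficulties within one acquisition.
* Dynamic routing is the original agreement rule only; EM or attention
  routing variants are out of scope.
* Trap anchors for partitioning full frames are inputs (a coordinate
  CSV); trap auto-detection is out of scope.
* At smoke scale the stochastic-training orderings hold with a one-point
  tolerance; single-seed differences between adjacent configurations are
  not statistically meaningful and are not treated as such.
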