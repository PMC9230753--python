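# Methods

## Problem and model

The package classifies a patient's paired left/right fundus photographs
into eight non-exclusive categories (N, D, G, C, A, H, M, O). The
pipeline is: weighted Gaussian enhancement → per-eye residual attention
CNN (shared weights) → two-branch fusion → dense head → per-class
probabilities, trained with label-smoothed cross entropy.

### Enhancement

`I_weight = α·I + β·blur(I) + γ` per channel, defaults α=4, β=−4,
γ=128, Gaussian blur 63×63 with σ=10 px in both directions. The blur is
computed separably with symmetric (reflective) border padding — a
reflective border avoids the dark halo a zero border would paint around
the bright fundus disc, and makes the transform commute exactly with
horizontal/vertical flips. The affine result can leave the 8-bit range,
so it is rounded and clipped to [0, 255]; with α = −β the response to
any constant image is exactly uniform 128, which the tests and the
acceptance script verify. The kernel is normalized to unit sum so the
blur is a weighted average.

### Residual attention block

For block input `F ∈ R^{C×H×W}`:

* `F′ = preconvs(F)`: `n_pre_convs` (default 3) channel-preserving 3×3
  conv+batchnorm+ReLU layers modelling cross-channel structure.
* Channel attention: `z = GAP(F′)`; two *independently parameterized*
  bottleneck dense maps (C → C/r → C) read the same pooled descriptor;
  their sum passes through ReLU (deliberately not sigmoid) and rescales
  `F′` channel-wise. The bottleneck ratio defaults to r=16; inside the
  backbone the effective ratio is capped so the bottleneck keeps at
  least 8 units, and the hidden layers start with bias 0.1 — very
  narrow ReLU bottlenecks otherwise have a realistic chance of starting
  with all units inactive, which silences their gradient.
* Spatial attention: the channel mean collapses `U` to `1×H×W`; a
  stride-1 3×3 max filter sharpens it (`P`); one 1→1 channel conv
  (default 7×7, same padding) produces the attention map which
  multiplies `P`; the product is broadcast over all C channels.
* Residual merge: `M = ReLU(U′ + F)`, shape `C×H×W`. The shape of every
  intermediate equals the block input's shape, which the merge requires;
  property tests assert this over random shapes.

With every attention parameter zeroed the block collapses to
`ReLU(F)`, so a zeroed-attention network equals an attention-free
backbone with the same residual weights — a useful structural check
that is asserted in the tests.

### Backbone variants

* `tiny`: 3×3/2 stem (16 ch) and three basic residual stages
  (32, 64, 128 ch, each stride 2), one attention block after every
  stage, global average pooling, linear projection to a 64-d embedding.
  A full forward pass at 64×64 takes well under a second on one CPU.
  The third stage exists for memorization capacity: with two stages the
  network underfits the small-area motifs (spots, lines, speckle) of
  the synthetic data.
* `resnet50`: bottleneck stages (3, 4, 6, 3; output 256–2048 ch) with a
  3×3/2 conv stem plus 3×3/2 max pool, attention after each stage,
  2048-d embedding. No pretrained weights are bundled;
  `pretrained=True` raises.

Both eyes share one branch by default (halves parameters and enforces
left/right symmetry: swapping the eyes with symmetric fusion weights
provably leaves the output unchanged, and a test asserts it).
Insertion points for attention blocks are configurable per stage.

### Fusion and head

`p = (1/T) Σ wᵢ yᵢ` with `T=2`, `w=(0.5, 0.5)` is applied literally, so
identical branch outputs yield `y/2`; the dense head after fusion makes
the overall scale immaterial. Three modes exist: `feature_average`
(default; fuse embeddings, then ReLU → dropout → dense → activation),
`feature_concat` (concatenate embeddings), and `prediction_average`
(per-branch heads, fuse probabilities). The head activation defaults to
sigmoid — the correct choice for independent multi-label outputs — with
softmax selectable.

### Loss and metrics

Targets are smoothed per class: `y′ = (1−v)·y + v/K`, v=0.1, K=8. The
default objective is per-class binary cross entropy on smoothed targets
(matching the sigmoid head); the categorical form `−Σ y′ log ŷ` is
selectable for the softmax head. Logs are natural — a different base
only rescales the loss — and probabilities are clamped at 1e−7 before
the log. Metrics are computed from per-class confusion counts with
threshold 0.5: accuracy (TP+TN)/total, precision TP/(TP+FP), recall
TP/(TP+FN), F1 2TP/(2TP+FP+FN); micro pools counts across classes,
macro averages per-class values, and zero denominators report 0 with a
warning. Reports always include per-class rows plus micro and macro
summaries.

### Split rule

Per class of size n the test set receives `round(n/5)` records
(nearest integer, ties to even). This is the unique simple rule
consistent with all eight published per-class train/test pairs
(574.6 → 575 rounds up, 307.8 → 308 rounds up, 151.2 → 151 rounds
down), and the full table is a regression test. Records are multi-label,
so the splitter walks classes in fixed label order, assigns each not-yet
-assigned record within a class pool at random (seeded), and never
reassigns — no patient can appear on both sides.

## Numerical engine

No deep-learning framework is used: `nn.py` implements the layers
(im2col convolution, batch normalization, dense, stride-1 and strided
max pooling, dropout, global average pooling) with explicit forward and
backward passes in float32, plus Adam (β₁=0.9, β₂=0.999, ε=1e−7,
Keras-style). Correctness is established by finite-difference gradient
checks through the entire network in the test suite. Everything is
deterministic given the seeds: weight initialization (He normal),
shuffling, dropout masks.

Batchnorm keeps running statistics as checkpoint buffers. Because
running averages lag quickly moving weights, training ends with a
calibration pass that re-estimates the statistics over the training set
(cumulative averaging, no gradient steps) before the checkpoint is
written; without it, inference-mode predictions can differ grossly from
training-mode behaviour on small fast-moving runs.

## Training engine

Defaults are the full-scale recipe: 256×256 inputs, Adam lr 0.001,
batch 32, 100 epochs, smoothed binary cross entropy. No early stopping;
a configurable validation fraction (default 10%) is carved from the
training manifest when no validation manifest is given, learning curves
are written per epoch, and the best-validation-loss weights are
checkpointed (with `val_fraction=0` the final weights are kept).
`epochs=0` checkpoints the initial weights with an empty history.
Checkpoints are self-describing: one `.npz` with all weights, buffers,
and the full configuration (backbone, fusion, enhancement, image size),
so `predict` rebuilds the exact pipeline from the file alone.

## Synthetic data

The generator emulates the external paired-eye dataset's layout
(CSV manifest `id,left_image,right_image,N,D,G,C,A,H,M,O`; one PNG per
eye) with schematic images: a bright orange disc, dark vessel-like
chords, and one colour- and shape-separated motif per disease (yellow
blobs D, pale inner disc G, concentric rings C, black spots A, red
lines H, cyan crescent M, magenta speckle O). The cataract motif is
deliberately high-frequency (rings rather than global haze) because the
63×63 background subtraction would erase a pure haze at small image
sizes. Disease bits are sampled per eye (default probability 0.22 per
disease, independent eyes) and the patient label is the union; N is
derived, set exactly when no disease is active. Rendering is a pure
function of (spec, patient index) via per-index spawned RNG streams, so
datasets are byte-reproducible and patient i does not depend on the
dataset size.

What the synthetic data does *not* emulate: real lesion morphology,
inter-class visual ambiguity, label noise, resolution variation, or
class imbalance at ODIR's scale. Passing the capacity test therefore
shows the pipeline can extract and fuse per-eye class signal end to
end — it says nothing about clinical performance on real photographs.

## Scale of the bundled experiments

The test suite and acceptance script train the tiny variant on 200
synthetic patients at 64×64 for 30 epochs with lr 0.01 and dropout 0 —
an overfit-capacity check (you do not regularize a memorization test),
chosen so the whole run takes about two minutes on one CPU. The model
reaches 100% training micro accuracy and F1 across seeds. The
full-scale defaults (256×256, lr 0.001, dropout 0.5, 100 epochs) are
the published recipe and are exercised structurally (a resnet50 forward
pass at 256×256) but not trained to convergence here.

## Known limitations

* The numpy engine is single-threaded-deterministic but slow at
  resnet50 scale; it is meant for study and small experiments, not GPU
  workloads.
* The published parameter count and headline ODIR metrics are out of
  scope: they require the external dataset and full-scale training.
* `prediction_average` fusion supports training, but the default and
  best-tested path is `feature_average`.
* Downsampling during class balancing is a seeded random subset; the
  original study does not state its reduction rule, so no fidelity is
  claimed for that step.
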