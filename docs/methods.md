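# Methods

## Problem setting

`seanet` detects objects that barely differ from their surroundings — the
regime of underwater imagery, where organisms camouflage against the
seabed, scene contrast is compressed by the water column, and a single
frame can contain both a large animal and one two orders of magnitude
smaller. The package implements a one-stage, anchor-free convolutional
detector whose three architectural ideas all target this regime, plus the
synthetic-scene benchmark and the degradation protocol used to exercise
it.

## Numerical core

No GPU tensor framework is used. The package is built on its own compact
reverse-mode autodiff core (`seanet.tensor`, `seanet.layers`,
`seanet.optim`): float32 numpy arrays on a dynamically recorded tape,
convolution lowered to window extraction + BLAS `tensordot` (with a
batched-matmul fast path for 1x1 convolutions), hand-derived backward
passes for group/batch normalisation and the classification losses, and
momentum SGD. Every primitive's gradient is validated against central
finite differences in the test suite. Single-threaded execution with
fixed seeds is bit-reproducible.

## Architecture

**Backbone.** A staged layer-aggregation backbone (stride-2 stem, four
stride-2 stages of CSP-style split-transform-merge blocks) exposing taps
at strides 8/16/32. Default stage widths (32, 64, 96, 192, 384) scale by
`width_mult`; the tiny profile uses 0.25. The internal block structure of
the aggregation baseline is not prescribed by the architecture this
package follows, so the CSP/BottleRep composition here is a deliberately
minimal stand-in; the package's claims attach to the three components
below, not to bit-level parity with any particular backbone.

**MDAM** (multi-scale detail amplification) replaces the body of the
stride-4 stage — early enough that fine texture survives. Five branches:
a shared 1x1 reduction feeds branch 1 (identity) and branches 2-4, which
stack a k x 1 / 1 x k asymmetric pair and a 3x3 convolution dilated at
rate k for k = (3, 5, 7) (the rule k_i = 2i - 1 for branch index i);
branch 5 is a 1x1 block on the *unreduced* input. Branches 2-5 each emit
a quarter of the reduced width, so their concatenation adds elementwise
to branch 1; a final 3x3 block maps to the output width. Conv blocks
here use group norm + ReLU (groups default 8, clipped to a divisor of
the width so tiny profiles normalise stably). Per-axis receptive-field
extents telescope to 3k + 2 (11/17/23 pixels): fine and broad context
are sampled simultaneously. The dilated kernel size is fixed at 3x3 —
the source material specifies only the dilation *rates* — following the
receptive-field-block lineage this design descends from. The
receptive-field oracle in the tests runs the block with `norm="none"`:
group normalisation couples all spatial positions through the shared
mean/variance, so with normalisation active the *gradient* support is
formally global even though the conv topology's window is 3k + 2.

**SE-FPN** fuses the three taps through four Contrast Enhancement Module
(CEM) nodes in a top-down then bottom-up pass (U4 from P6 + up(P9); D1
from P4 + up(U4); D2 from down(D1) + U4 + P6; D3 from down(D2) + P9).
Fusion is plain concatenation — no learned fusion weights — and
alignment hops are nearest-neighbour x2 + 1x1 conv (up) or stride-2 3x3
conv (down). The exact graph is a reconstruction: the source describes
cross-scale concatenation of previous-layer features and four fusion
nodes with three outputs, and the graph used here is the minimal one
consistent with that; it is a design choice of this package, with one
backbone skip (P6 into D2).

**CEM** = SCAM pre-attention, then two parallel branches: a 1x1 block
whose output passes through the fore/background contrast attention (FBC)
with a residual add, and a 1x1 block followed by three BottleRep
residual blocks, every intermediate collected and fused by a final 1x1
block (concat width = 4 x hidden). Conv blocks in the neck use batch
norm + SiLU — deliberately different from MDAM's group-norm/ReLU blocks;
the two conventions are honoured per context.

**FBC** is the package's centrepiece attention. A 1-channel 1x1 conv +
batch norm + leaky ReLU, squashed by a sigmoid, yields a foreground
activation map Ff in (0,1) of shape [B, 1, H, W]; Fb = 1 - Ff is the
background map. Flattening and matrix-multiplying each map against the
feature map pools two channel descriptors vf, vb of shape [B, 1, C];
each is gated by an affine map + sigmoid into cf, cb; the output is
F' = F * (cf - cb), broadcast over space. Channels that respond more to
foreground than to background are amplified, background-dominated
channels suppressed. The two gating maps are independent by default
(symmetry between foreground and background must be breakable by
training; the printed formulation reuses one map ρ, and `shared_gate=True`
reproduces that reading, under which a zero pre-activation map forces
cf = cb and an exactly zero output).

**SCAM** internals are reconstructed from the stated order (channel
attention, then spatial attention, combined): channel gate = shared
two-layer bottleneck over global average- and max-pooled descriptors,
summed, sigmoid; spatial gate = 7x7 conv over the channelwise mean/max
maps, sigmoid; applied sequentially.

**Head and loss.** Anchor-free head at strides 8/16/32; per level, two
3x3 conv-block towers (classification and regression) feed 1x1
projections: each cell predicts class logits and, per box side, a
16-bin discrete offset distribution (reg_max = 16, the standard
convention). Boxes decode as
the softmax expectation per side, in stride units from the cell centre.
Training targets come from task-aligned assignment (metric
score^0.5 * IoU^6, top-10 candidates per ground-truth box, centre-inside
prior; ties to the highest-IoU box), with soft target scores rescaled so
each box's best anchor scores that box's best IoU. The composite loss is

    total = 7.5 * box + 0.5 * cls + 1.5 * dfl

with box = sum (1 - CIoU) * w / S, dfl = sum DFL * w / S,
S = max(sum target_scores, 1), and w the matched anchor's target score.
The classification term is, by default, binary cross-entropy over *all*
anchor-class pairs against the soft target map divided by S — the
baseline convention this loss configuration retains, which scales
stably with anchor count; the literal unnormalised sum over matched
anchors only is available via `cls_mode="matched_sum"`. CIoU's
aspect-term coefficient alpha is treated as a constant under
backpropagation (its reference treatment). Following the same reference
convention, the optimiser objective is the (already normalised) batch
loss multiplied by the batch size; the logged breakdown stores the
unscaled components, and the 7.5/0.5/1.5 identity is asserted on every
step.

## Evaluation

COCO-style: greedy score-ordered one-to-one matching per class at a
given IoU threshold; 101-point interpolated average precision; headline
AP averages IoU thresholds 0.50:0.05:0.95, with AP50/AP75 at fixed
thresholds. Precision/recall/F1 (F1 = 2PR/(P+R)) are reported at the
confidence threshold maximising F1 at IoU 0.5, macro-averaged over
classes (whether the reference numbers are micro- or macro-averaged is
unstated; macro is this package's choice). Inference uses a 0.001
confidence floor and class-wise greedy NMS at IoU 0.7, boxes clipped to
the image — the usual one-stage evaluation settings, which the source
leaves unprinted.

## Synthetic scenes

The generator emulates the statistics that make the target imagery hard,
not its photometry (no haze or colour-cast simulation — those belong to
the enhancement literature, not this detection protocol):

* background: multi-octave smooth value noise (octaves 4/8/16/32),
  tanh-squashed, mapped to intensity 0.45 +- 0.18, with a fixed
  blue-green colour cast;
* objects: 1-15 per scene with mean 9.57 (1 + Binomial(14, p) with p set
  from the mean — the per-image instance profile of large reef survey
  datasets); box areas log-uniform over 0.5%-20% of the image (the span
  between a small fish and a large turtle sharing a frame);
* contrast: each object's interior carries the *same* texture field as
  the background, shifted in mean intensity by `contrast_delta` with a
  random sign per object — at delta 0 objects are pixel-identical to the
  background, so difficulty is controlled by a single number;
* classes are shape families (elongated ellipse / lumpy blob / star),
  never intensity, so class stays decodable as delta -> 0. Family
  parameters are bounded away from each other (ellipse aspect >= 1.5,
  blob harmonic amplitudes floored) so that the families are disjoint by
  construction — a circle would be both a degenerate ellipse and a
  degenerate blob, making class labels unlearnable;
* objects are painted large-first; each annotation box is the tight
  bbox of the pixels the object actually owns in the final image
  (heavily occluded objects with fewer than 4 visible pixels are
  dropped), so the emitted box always equals the rendered mask's bbox
  exactly.

Scene synthesis is bit-deterministic in (spec, seed). What passing tests
on these scenes do *not* show: robustness to real-water photometry
(wavelength-dependent attenuation, haze, lighting), to label noise, or
to natural object textures; the generator controls contrast and scale
statistics only.

**Degradations** follow a five-level severity ladder applied to
evaluation images only, after annotation: Gaussian noise with standard
deviation {10, 20, 30, 40, 50} on the 0-255 scale (added, rounded,
clipped — the 0-255 reading of the quoted deviations), and motion blur
by a normalised 1-D line kernel of size {5, 9, 13, 17, 21} (horizontal
by default; the angle is configurable since the source does not state
one), convolved with nearest-edge padding.

The contrast-fidelity measurement (`measured_contrast_gap`) renders a
scene twice with the identical random stream, once as requested and once
at delta 0, and averages the foreground intensity shift. The pairing is
deliberate: comparing spatial means of *different* image regions would
confound object visibility with sampling noise of the (spatially
correlated) background texture.

## Training protocol

Defaults mirror the reference protocol: 640-pixel inputs, batch 16, SGD
(momentum 0.937, weight decay 5e-4 applied to conv/linear weights only —
norm gains and biases are exempt, the usual trainer convention), initial
LR 0.01, 300 epochs, seed
0, mosaic augmentation (2x2 around a random centre, boxes remapped and
dropped under 10% surviving area) disabled for the final 10 epochs, no
pre-trained weights, early stopping on validation AP50 with patience 50
(the metric and patience are this package's choice; both are unprinted).
The LR schedule is 3-epoch linear warmup then cosine decay to 1% — the
usual one-stage convention, also unprinted. Validation runs on an
exponential moving average of the weights (decay 0.999 with a ramp),
another convention of the baseline family's trainers; `use_ema=False`
disables it.

The **tiny profile** used throughout the tests is explicit about its
overrides: quarter widths, 160-pixel scenes, batch 4, initial LR 0.025
(short schedules at quarter width need a faster effective rate; the
full-profile defaults stay at the reference values), no early stopping.
Its problem sizes — 200 training scenes, 60 held-out scenes, 30 epochs —
are the package's CPU-scale experimental conditions: large enough for
the easy/low-contrast difficulty ordering and the degradation ladder to
be resolvable, small enough to iterate on a single core. End-to-end
learning checks train on the easy split (delta 0.6) and compare against
a matched-budget run at delta 0.15; the robustness sweep reuses the easy
model across both degradation kinds x severities 1-5.

## Numerical choices and degenerate inputs

* float32 weights/activations; evaluation metrics in float64.
* Group count for group norm: min(8, C) reduced to a divisor of C.
* Sigmoid computed as (1 + tanh(x/2))/2 (overflow-free).
* DFL targets outside [0, reg_max - 1] are clamped with a warning;
  matched-side offsets are clipped at reg_max - 1 - 1e-3.
* Empty assignments: box and dfl terms are exactly 0; the normaliser S
  floors at 1; classification is computed against an all-zero target map.
* Degenerate (zero-area) boxes are rejected by `ciou`; classes without
  ground truth are excluded from macro averages; all-zero confusion
  counts report P = R = F1 = 0 with a degenerate flag.
* Elementwise max/min route gradients to the first argument on ties.
* NMS ties and ordering are resolved by descending score, stable.

## Known limitations

* The backbone is a minimal stand-in, not a replica of any published
  aggregation network; parameter counts are not comparable to published
  model sizes.
* The synthetic benchmark cannot validate photometric robustness or
  class semantics beyond shape; transfer to real imagery is untested.
* CPU training limits the regime to tiny profiles; reported AP values
  on synthetic scenes are not comparable to benchmark AP on real
  datasets.
* The assigner resolves multi-box conflicts per anchor by IoU, which can
  starve a heavily-overlapped small object in extreme crowding.
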