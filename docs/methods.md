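# Methods

## Problem and approach

Estrus in sows lasts roughly 40–60 h of a ~21-day cycle, and insemination
must be timed within about a day of ovulation, so timely detection drives
reproductive efficiency (piglets weaned per sow per year). Two visible
vulvar changes accompany estrus: congestion deepens the mucosal red, and
edema rounds the outline. `sowestrus` implements a two-stage pipeline
around exactly those cues:

1. **Localisation.** A compact single-class detector finds the vulva
   bounding box.
2. **Interpretable classification.** Two features are computed from the
   box — aspect ratio AR = h/w in pixels, and the mean HSV S-channel
   value over pixels passing a dual red-hue mask — and a small MLP maps
   them to an estrus probability.

The split keeps the decision auditable: every call can be traced to a
shape and a color measurement rather than an end-to-end black box.

## Synthetic scenes in place of farm imagery

The farm imagery this kind of system is trained on is commercially
restricted, so the package ships a generator (`scenegen`) that renders
one elliptical vulva-like region over low-saturation gray-brown clutter.
Label-conditional feature distributions follow the published group
statistics:

| group | aspect ratio | red saturation |
|---|---|---|
| estrus | 0.682 ± 0.272 | 87.010 ± 9.777 |
| non-estrus | 0.973 ± 0.314 | 73.621 ± 11.661 |

Draws are truncated normals (resample-until-valid; AR in (0.1, 3.0),
saturation in [0, 255]). Truncation shifts the estrus AR mean upward by
about +0.011; sampling tests therefore compare against the exact
truncated-normal mean (scipy `truncnorm`) rather than the raw printed
mean. Hue is drawn from the red windows themselves, value from
140–220, and the background's chroma is kept well below the S ≥ 50 mask
gate so background pixels can never enter the saturation statistic.
Nuisances — vertical occlusion bars (0–2), Gaussian blur (σ ∈ {0, 1, 2}
px), lighting variation via the background/value draws — are applied
*after* the ground-truth box is fixed, mimicking the failure modes seen
in the field (occlusion, blur, weak color).

Datasets assign scenes to sows round-robin; each sow carries a persistent
label, and the train/val/test split is stratified by label at the **sow**
level in an 8:1:1 ratio so no animal's images leak across splits.

What the generator does *not* emulate: real tissue texture, specular
glare, fecal contamination, multiple animals, perspective distortion, and
inflammation-induced redness. Passing tests therefore demonstrate that
the algorithms are implemented correctly and behave as designed on data
with the published feature statistics — not that the system reaches
field-grade accuracy on real sows.

An important consequence of honoring the published group statistics: the
two class-conditional feature distributions overlap substantially
(Mahalanobis distance ≈ 1.6 treating the features as independent
normals), which caps any classifier at a Bayes accuracy of ≈ 0.79 at
equal priors (≈ 0.82 at the 30 % estrus prevalence used here) and an
AUC-ROC of ≈ 0.87. The synthetic end-to-end accuracy observed (~0.80)
sits at that ceiling. Note these same published statistics are hard to
reconcile with the published rank statistic for the aspect ratio
(U = 826 over 148 × 350 pairs implies near-complete separation); the
generator follows the group means/SDs and does not attempt to reconcile
the two.

## Detector

**Backbone.** A small strided convolutional stack (3×3 convs, batch
norm, GELU) emitting four levels C2–C5 at strides 4/8/16/32. It is
deliberately a stand-in: the package's contribution is the neck and
head, and every width is configurable (`DetectorConfig`).

**SDI fusion gates.** Each gate fuses 2–3 same-shape maps as
F_out = Σᵢ (αᵢ/Σⱼ αⱼ) · Att(Fᵢ) with learnable non-negative scalars αᵢ
(ReLU-rectified before normalisation, so the weights always sum to 1 and
the fusion is invariant to rescaling all α). Att is a channel attention
built from four squeeze-excite heads (global average pool → bias-free
bottleneck → sigmoid), whose gates are averaged; the heads are shared
across the inputs of a gate, which is what keeps the reference
parameter count at 4 · 2 · 128 · 24 = 24,576 ≈ 24.6 k per gate.

**Neck.** Five gates over the four levels in a bidirectional layout —
top-down fusions at P4 and P3 (two nearest-neighbour ×2 up-samplings),
then bottom-up fusions at P3, P4 and P5 (three 2×2 down-samplings).
Down-sampling is 2×2 average pooling and up-sampling nearest-neighbour,
both parameter-free; this is a deliberate design choice so that the
neck's learnable budget consists of its five gates alone (0.12 M at the
128-channel reference width), matching the published accounting.

**Head.** P5 is up-sampled to the P4 grid and channel-aligned; P4 and
the aligned P5 are then brought to the P3 grid and concatenated with P3
(3c channels), followed by two 1×1 convolutions (3c → c → c, GELU +
batch norm; 65,792 parameters at c = 128) and a 1×1 single-class
projection to 5 channels per cell: sigmoid in-cell centre offsets,
sigmoid width/height as image fractions, and an objectness logit.

**Training.** Binary cross-entropy on objectness (positive cells
up-weighted ×8) plus masked MSE on the box channels at the positive cell
(weight 5), Adam, batch 16. The scaled-down runs use 64×64 inputs,
15 epochs and a cosine decay from 2·10⁻³ to 10⁻⁴ — sizes chosen so the
whole synthetic study (1400 scenes) trains in a couple of minutes on one
CPU core while comfortably clearing the mAP@0.5 = 0.8 gate. Inference
thresholds objectness at 0.3 and applies greedy IoU-0.5 NMS.

**Complexity accounting.** `count_complexity` reports exact learnable
parameter counts per block and FLOPs as 2 × multiply–adds of conv/dense
layers at the stated input size; biases and normalisation are excluded
from FLOPs. This convention must be stated because published FLOP
figures rarely specify it.

All networks run on a small reverse-mode autodiff engine written for
this package (`sowestrus.nn`, float64, im2col convolutions). At these
model sizes a dedicated engine is simpler and more portable than a deep
learning framework dependency, and its gradients are verified against
numerical differentiation in the test suite.

## Distillation

Masked generative distillation between a trained teacher detector and a
narrower student: per distillation layer, a per-pixel binary mask
(rate λ, shared across channels, independent across layers and steps)
multiplies the channel-aligned student features, and a generator (1×1
align + two 3×3 convs with ReLU) must regenerate the teacher's features;
the loss is the summed squared error. As printed, the loss formula lacks
the square; the squared-L2 form of the original MGD method is used. The
hook points are the three neck outputs (the head's inputs). Defaults:
λ = 0.5, distillation weight 1.0 with the reconstruction error
normalised per feature element (so task and distillation terms share a
scale), teacher frozen. The scaled-down paired experiment (three seeds,
320 training scenes, 15 epochs) shows a consistent but small mAP
improvement of the distilled student over its identically trained
undistilled twin — at desk scale the effect is real but modest, a few
points at most.

The learning-rate schedule is implemented exactly as the closed form:
η(t) = 10⁻⁴ + 9·10⁻⁴·t/3 for 0 ≤ t < 3, then
10⁻⁶ + ½(10⁻³ − 10⁻⁶)(1 + cos(π(t−3)/297)) for 3 ≤ t < 300; both
branches meet at 10⁻³.

## Features

Crops use rounded half-open pixel bounds clipped to the image. HSV
follows the 0–180 / 0–255 / 0–255 integer convention so the thresholds
apply verbatim: the red mask is (H ∈ [0,10] ∪ [160,180]) ∧ S ≥ 50 ∧
V ≥ 50, both hue windows closed. Red saturation is the mean S over the
masked pixels of the full crop; when no pixel passes, the value 0 is
returned with an explicit `no_red` flag so downstream code can treat it
as missing rather than as genuinely zero (the degenerate case is not
covered by the published description; this convention is ours). Aspect
ratio is pixel height over pixel width of the box, which makes it
invariant to joint image-and-box rescaling but — deliberately — not to
anisotropic resizing.

## Classifier

MLP 2 → 16 → 8 → 1, ReLU hidden, sigmoid output, decision threshold 0.5.
Features are min-max normalised with statistics from the training split;
out-of-range test values are clipped to [0, 1] with a warning.
Training: binary cross-entropy, Adam (lr 10⁻²), batch 32, 300 epochs,
fixed-seed shuffling (deterministic per seed). Pruning is unstructured
magnitude pruning over all layers jointly: λ is either given or taken as
the target-sparsity quantile of |W|; weights with |w| ≤ λ are zeroed, the
zero pattern is enforced during a short fine-tune (30 epochs), and a
threshold that would zero every weight is rejected. At 50 % sparsity the
fine-tuned model gives up at most ~2 accuracy points on the synthetic
task.

## Metrics

Single-class mAP@0.5 uses greedy confidence-ordered one-to-one matching
at IoU > 0.5 (duplicates on an already-matched truth are false
positives) and all-point interpolation of the precision envelope —
the modern detection convention rather than 11-point sampling.
AUC-ROC/AUC-PR delegate to scikit-learn (average precision is the
all-point PR area). The Mann-Whitney U is reported as min(U₁, U₂) with
midrank ties (the convention under which the published U = 826 is the
smaller statistic), and the rank-biserial effect size r = 1 − 2U/(n₁n₂)
is reported as a magnitude. Cohen's d (pooled SD) appears in the group
summary for completeness but is not asserted against published values,
whose derivation is not reproducible from the printed group statistics.

## Pipeline

Per frame: detect → keep the highest-confidence box (one vulva per frame
by protocol; extra boxes are logged) → area guard → features → classify
→ annotate. The guard skips classification when the box covers less
than `min_box_fraction` (default 1 %, the published rule states the
guard but no value) of the frame and annotates it blue to prompt the
operator to move closer; green marks non-estrus, red estrus. A
training-free reference detector (largest connected component of the red
mask) provides a detector-independent fallback and cross-check.

## Numerical choices and degenerate inputs

- Zero-area boxes: IoU warns and returns 0; zero-area crops are
  rejected.
- Empty confusion denominators: NaN with a warning, never a silent 0;
  undefined F1 reported as 0 with a warning.
- Ellipses that cannot fit the frame at the sampled aspect ratio are
  shrunk isotropically (AR preserved); degenerate (zero-axis) ellipses
  are rejected.
- Batch norm uses batch statistics in training and running statistics
  (momentum 0.1) in evaluation; ε = 10⁻⁵.
- All randomness flows through explicit `numpy.random.Generator`
  instances; dataset builds are bit-reproducible per seed.

## Known limitations

- The backbone is not a production detector; absolute mAP numbers on
  real imagery are out of scope.
- The GELU used everywhere is the tanh approximation; it is *not*
  monotone left of its minimum near x ≈ −0.75 (tests assert its true
  shape).
- The distillation benefit at desk scale is small relative to seed
  noise; the paired experiment uses fixed seeds and a fixed dataset.
- Saturation is computed over the full crop (including corner background
  pixels, which the mask excludes by construction); an inscribed-region
  variant was not implemented.
- Video I/O is out of scope; the pipeline contract is per-image.
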