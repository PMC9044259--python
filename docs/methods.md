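# Methods

`wheatear` implements a lightweight single-stage, anchor-based detector for
wheat ears (the grain-bearing spikes) in top-down field imagery, together
with a synthetic scene generator so that the complete pipeline — data,
training, inference, evaluation — runs on a desktop CPU with no external
dataset. This note records the model, the choices that were genuinely open,
the numerical details, and what the synthetic experiments do and do not
demonstrate.

## Model

**Backbone.** A stem convolution (3×3, stride 2, 16 channels, batch norm +
TanhExp) followed by fifteen AsymmBottleneck (ASB) stages. An ASB stage is
an inverted residual block in which the 1×1 expansion produces only
`exp_size − C_in` new channels; the input channels are concatenated
alongside them unchanged, so the depthwise convolution still works at width
`exp_size` while the expansion convolution shrinks by a factor
`C_in/exp_size`. Batch normalisation follows every convolution; TanhExp
follows the expansion and depthwise stages; the final 1×1 projection is
linear (a standard linear bottleneck); a residual connection is added when
stride is 1 and input and output widths agree. Eight of the fifteen stages
carry an SPSA attention block (the three 40-channel stages, the two
112-channel stages and the three 160-channel stages), placed after the
depthwise convolution and before the projection — the position
squeeze-excitation occupies in the mobile blocks this family descends
from. Three stage outputs are tapped as a feature pyramid: P3 (stride 8,
40 ch), P4 (stride 16, 112 ch), P5 (stride 32, 160 ch).

The stage table lists the 12th stage (64×64×112 output) as the P4 tap.
Reading the P4 tap one stage later would place P4 at stride 32, colliding
with P5 and breaking the 8/16/32 pyramid the neck requires, so the
12th-stage tap is used.

**TanhExp.** f(x) = x·tanh(eˣ). For x ≥ 1 the deviation from the identity
never exceeds 0.01 (the measured maximum on [1, 10] is ≈ 0.0087 at x = 1);
the negative lobe is bounded (minimum ≈ −0.353). Above x = 20,
tanh(eˣ) = 1 to double precision, so the implementation switches to the
identity there — exact, and immune to the eˣ overflow a naive evaluation
hits near x ≈ 709. The derivative is supplied analytically to the autodiff
engine with the same large-x branch.

**SPSA (shuffle polarized self-attention).** Channels are split into G
groups (default G = 2); each group is halved into a channel-only and a
spatial-only polarized attention branch; outputs are concatenated and a
channel shuffle (the (G, C/G) transpose permutation) mixes information
across groups. "Polarized" means one axis is collapsed completely while
the other keeps full resolution. With internal width c_i = c/2:

- channel branch: A = σ(W_z(V q)), V = reshape(W_v x) ∈ R^{c_i×HW},
  q = softmax(flatten(W_q x)) ∈ R^{HW}; output A ⊙ x per channel.
- spatial branch: A = σ(reshape(q V)), q = softmax(GAP(W_q x)) ∈ R^{c_i},
  V = reshape(W_v x) ∈ R^{c_i×HW}; output A ⊙ x per position.

Open points resolved as package choices: the gate F_SG is the logistic
sigmoid; the internal projection width is half the branch width
("compress, then boost"); no layer normalisation after the gate (exposed
nowhere — the block is bias-free so the all-zero input maps to all-zero
output exactly, which the tests exploit); projections are bias-free 1×1
convolutions with Kaiming-uniform initialisation under a caller-supplied
seed.

**Neck and heads.** A PANet-style aggregation with one 1×1 fusion per
junction: top-down (nearest-neighbour ×2 upsample, concatenate, fuse) then
bottom-up (3×3 stride-2 convolution down, concatenate, fuse). Default
per-level widths mirror the backbone taps (40, 112, 160) to keep the model
small. Each level ends in a 1×1 head emitting 3 anchors × (tx, ty, tw,
th, objectness, class) = 18 channels; the single class (wheat ear) keeps
its logit for API generality. Decoding is the standard grid
parameterisation: centre = (sigmoid(t) + cell)·stride, size =
anchor·exp(t) (t clamped at 8 before exponentiation), confidence =
σ(obj)·σ(cls), boxes clipped to the image.

**Anchors.** Nine (w, h) priors, three per level, smallest to P3. With
training data they are fitted by k-means under the 1 − IoU distance on
centred boxes (deterministic quantile initialisation, Lloyd refinement);
without data a built-in compact square-ish set spanning 16–256 px is used.
When the size distribution of a dataset is narrow, fitted anchors collapse
to nine similar shapes, which spreads near-identical priors across all
three strides and assigns targets to grids too coarse to localise them —
in that regime the spread default set trains markedly better, and the
training-recovery test uses it.

## Losses and assignment

Box regression uses the CIoU loss

    L_CIoU = 1 − IoU + ρ²/c² + αν,
    ν = (4/π²)(arctan(w_gt/h_gt) − arctan(w/h))²,  α = ν/((1 − IoU) + ν),

with ρ the centre distance and c the enclosing-box diagonal; α is held
constant within a step (standard practice). IoU and GIoU losses are
provided for comparison and share the scalar geometry (half-open
continuous coordinates, area (x2−x1)(y2−y1), no +1).

Assignment is YOLOv3-style: each ground-truth box goes to its best-IoU
anchor (centred width/height IoU over all nine priors) at the grid cell
containing its centre; other anchors reaching IoU ≥ 0.5 (the configured
threshold) are also positive; cell collisions are first-come-first-served
in ground-truth order. Positive objectness targets are 1, not
IoU-weighted.

The composite loss has four terms with weights (box 5, objectness 1,
class 1, band-box 1):

- **Box**: mean CIoU over the assigned positives.
- **Objectness BCE** over three cell populations per level. Positives
  share an aggregate weight of 0.5 (per-cell weight 0.5/n_pos, so the
  handful of positive cells is never drowned by the grid). Each true
  background cell gets one tenth of the per-positive weight — a *per-cell*
  force, not a population balance: with a population-balanced background
  weight (0.5/n_neg ≈ 10⁻⁴ per cell) the objectness head generalises
  upward from the positives and empty background ends up firing at
  confidence ~0.4; the stronger per-cell pressure is safe because
  background features genuinely differ from object features. Cells in the
  *ignore band* — anchor-cells whose centre lies inside a ground-truth box
  without being the assigned cell — carry no objectness loss at all:
  they share features with the adjacent positive cell, and every variant
  that pushed them down with comparable force dragged the positives
  below the detection threshold and collapsed recall.
- **Band box**: band cells are regressed (CIoU) towards the containing
  ground-truth box translated to their own cell centre — the closest box
  the in-cell sigmoid decode can represent. Whatever fires on the band
  then duplicates the true detection closely enough for NMS to remove it.
- **Class BCE**: positives target 1; band cells target 0.5 (optimum at a
  zero logit, with the ln 2 entropy floor subtracted so the term is zero
  at its optimum). The soft target caps duplicate confidence near half
  the positives' while leaving enough headroom that the (more numerous)
  band cells cannot drag the shared features down; the two populations
  carry equal aggregate weight in this term for the same reason.

The ignore-band treatment, the per-cell background weight and the soft
band class target were each selected against the alternatives (plain mean
BCE, population-balanced negatives, hard 0 band targets, band cells as
hard negatives) on the synthetic recovery benchmark, where the rejected
variants either let false positives flood the ranking or collapsed
recall.

## Evaluation

Greedy confidence-ordered matching with one-to-one highest-IoU pairing at
threshold 0.5; ties on IoU break to the lower ground-truth index.
Precision = TP/(TP+FP), recall = TP/(TP+FN). AP integrates the precision
upper-envelope over recall (all-point interpolation, the literal reading
of AP = ∫P dR; not the 11-point variant). With one class, mAP = AP. The
greedy matcher is pinned as the package's definition; on random ≤ 5-box
instances it agreed with exhaustive optimal matching in every tested case.
NMS is greedy by confidence with an IoU ≥ threshold suppression rule
(default 0.45).

## Synthetic data

The generator emulates the geometry and statistics of wheat-head imagery,
not its photometry: 20–70 ears per scene (uniform; mean ≈ 45), rendered as
oriented textured ellipses with banded "spikelet" shading and a few awn
strokes, over a smoothly varying green-brown background with noise.
Lengths are 5–11 % of the image side with aspect ratio 2.2–3.6, mixed
orientations, and clumped placement that produces genuine occlusion. Boxes
are the tight axis-aligned extent of the rendered pixels (ellipse plus
awns), so labels and geometry agree by construction. Everything is a pure
function of (config, seed).

An `easy_config` preset exists for training-recovery checks: 3–8 large
non-overlapping ears on a dissimilar background at 256². What passing the
recovery test shows is that the full pipeline — rendering, assignment,
differentiation through backbone/neck/heads, CIoU/BCE optimisation,
decoding, NMS, AP — is wired correctly end to end. It does not show
field-ready accuracy: real canopies have photometric variation, motion
blur, dense occlusion and label noise the generator deliberately omits.

Augmentations: mirror (exact box reflection), scale (bilinear zoom, boxes
multiplied), rotation within ±15° (boxes become the clipped tight hull of
their rotated corners; areas below 4 px² are dropped), saturation
(colourfulness rescaling, boxes untouched), and 4-scene mosaic around a
random centre with translation remapping and clipping. The batched
training loop applies mirror/rotate/saturation and mosaic on the fly;
scale is excluded there because it changes the tensor size mid-batch (it
remains available through the augmentation API).

## Training

Adam with L2 weight decay; cosine-annealed learning rate from the initial
value to 0.2× it at the final epoch (the "cosine annealing parameter").
Reference defaults mirror the recipe the detector is designed for: input
1024², batch 4, 100 epochs, lr 0.01, weight decay 5·10⁻⁴, assignment IoU
threshold 0.5. "Maximum number of iterations 100" is read as 100 epochs.
Head objectness biases start at −4 so a fresh model is near-silent instead
of flooding NMS. NaN loss aborts with a diagnostic. Checkpoints are
`.npz` state dicts plus JSON metadata; save/load round-trips are
bit-exact.

All tensors are float32; the numerical test-bench runs the same ops in
float64 for central-difference gradient checks (every convolution path,
softmax, indexing, BCE, the TanhExp derivative).

## Problem sizes used in the test suite

Desk-scale sizes keep the suite fast while exercising every code path:
the structural checks run the full-width backbone once at 1024² (≈ 5 s);
training tests use a width-0.5 model (channel counts scaled by half,
rounded to multiples of 8) at 256² on 64 easy scenes for 26 epochs, and a
width-0.25 model for quick probes. The rasterization oracle for the box
losses counts pixel centres on a 1000×1000 grid over 200 random pairs.

## Known limitations

- The generator's realism is deliberately minimal; no claim is made about
  transfer to real field imagery without retraining.
- Training throughput is CPU-bound NumPy; the reference 1024²/100-epoch
  recipe is expressed in the defaults but is not practical without
  substantial compute.
- Single-image batch statistics make batch norm noisy in the overfit
  probe; its loss trace trends firmly downward but is not monotone at
  every step (no first-order stochastic optimiser is).
- Greedy NMS and greedy matching are pinned conventions; both can differ
  from globally optimal alternatives on adversarial configurations.
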