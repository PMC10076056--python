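# Methods

`paddycount` estimates the number, positions and sizes of plants in
nadir RGB imagery of a transplanted field (the motivating case is rice
between tillering and jointing, photographed from a low-altitude UAV),
using only dot annotations of plant centers for supervision.  This note
records the model, its assumptions, the parameters that matter, and the
numerical and design choices behind the implementation.

## Counting by density regression

The supervision signal is a ground-truth density map.  For an image with
plant centers $x_1,\dots,x_N$ the target is

$$D^{gt}(x) = \sum_{i=1}^{N} \delta(x - x_i) * G_\sigma(x),$$

a sum of isotropic Gaussians, so that $\int D^{gt} = N$ and a regressor
of $D^{gt}$ counts by integration.  Targets live on a grid at **half**
the input resolution (annotation coordinates are halved before kernel
placement), matching the resolution of the network's density output.

Numerical choices:

* each kernel is **truncated at 4σ** (mass beyond is < 1e-4) and
  **renormalized to unit mass after boundary clipping**, so the
  count-integral identity holds exactly (to 1e-6) even for plants at the
  image border.  Construction is O(N·σ²);
* the Gaussian is normalized to unit mass (counting by integration
  requires it);
* default **σ = 6** grid cells.  Counting accuracy is insensitive to σ
  in the 2–8 range; 6 is the default and σ is a config field.

The binary attention target is the thresholded support of the density
target: 1 where $D^{gt} > 0.001$, else 0.

## Network

A VGG-16-with-batch-norm style encoder — thirteen 3×3 convolutions in
blocks of widths 64/128/256/512 with 2×2 max pools — yields a pyramid
L1..L4 at strides 2/4/8/16 (L1–L3 are the pool outputs of blocks 1–3;
L4 is the block-5 output).  Two structurally identical decoder branches
walk back up the pyramid; each step bilinearly upsamples ×2,
concatenates the skip level, and applies two 3×3 conv+BN+ReLU layers
("parsers"); the heads add a 1×1 projection to one channel.  The density
branch ends in a ReLU (density is non-negative) giving the initial
density map IDM; the attention branch ends in a logistic squashing
giving the plant attention map PAM ∈ [0,1].  The refinement is

$$\mathrm{FDM} = \mathrm{ReLU}(\mathrm{Conv}_{1\times1}(\mathrm{PAM} \odot \mathrm{IDM})),$$

initialized to the identity (weight 1, bias 0) so training starts from
FDM = PAM·IDM.  The predicted count is the integral of FDM.

The size head (PSE) applies two 3×3 conv+BN+ReLU layers to L4, adaptive
2×2 average pooling, and two linear layers, ending in a **softplus**.
Softplus rather than ReLU is essential here: a randomly initialized head
behind an output ReLU emits exactly 0 with zero gradient — a dead unit
that stage-2 training can never revive — whereas softplus is
non-negative with a nowhere-zero gradient.

Open design points, fixed as follows: "several convolutions" per parser
means two; "merge" means channel concatenation; upsampling is bilinear
with align-corners off; the refinement convolution is a single 1×1; the
output activations are as above (none of these is forced by the method's
definition; they are the smallest consistent choices).  Inputs are
zero-padded to a multiple of 16.

The network is implemented on a small self-contained numpy layer stack
(`paddycount.nn`) with explicit backward passes and Adam; tensors are
channels-last, and convolutions are computed as k² shifted matrix
products, which profiles ~3× faster than an im2col patch matrix on one
CPU at these widths.  Two presets share the topology: `full` (widths
above) and `tiny` (widths ÷ 8), the latter fast enough to train on a
single CPU and used by every training experiment in the test suite.

## Losses

Stage 1 minimizes

$$L = L_{mse} + \lambda\, L_{bce} + \gamma\, L_{si},\qquad \lambda = \gamma = 0.1,$$

where $L_{mse}$ is the mean squared error FDM vs. target, $L_{bce}$ the
per-pixel binary cross entropy PAM vs. attention target, and $L_{si}$
the positive–negative counting loss: with the positive region
P = {gt > 0} (the exact support, independent of the 0.001 attention
threshold), object probability $p$ on P (default 1) and background
probability 1 off P,

$$C^O = \textstyle\sum_m P^O_m\,\hat D_m,\quad C^B = \sum_m P^B_m\,\hat D_m,\quad
L_{si} = \lvert (C^{gt} - C^O) - C^B \rvert.$$

$L_{si}$ is implemented exactly in this form, including its known
cancellation property (a positive-region deficit can be offset by
background mass; the tests document a worked case).  During patch
training $C^{gt}$ is the **crop-local** count — the only locally
coherent choice.  BCE is averaged over pixels (a scale-free reduction;
a strict summation variant is available).  Probabilities are clamped at
1e-7 before logarithms.

Stage 2 minimizes the L1 distance between the regressed size limit
$d_p$ and the per-image pseudo-average plant size (below), fine-tuning
the encoder as well.

## Localization and sizing

**Pseudo-size.**  For annotated points, each plant's initial size is
$\bar x_j = \frac{\beta}{K}\sum_{k=1}^{K} x_{j,k}$ (mean distance to its
K nearest neighbours, scaled by β), and $D_{mean}$ is the average over
plants.  Defaults K = 3, β = 0.8.  Under the even-spacing assumption of
a transplanted stand this is a usable size supervision without box
labels.  Ties in neighbour distance are resolved by (distance, index)
order; the tie choice cannot change the result, because tied distances
contribute equal values.

**LNMS.**  Plant centers are the cells of the FDM that equal the
maximum of their w×w neighbourhood, with w = round(0.3·D_mean) coerced
to the nearest odd integer ≥ 3 (an odd window gives a symmetric
neighbourhood; D_mean is expressed in density-grid cells here).
Candidates at or below 0.3 × (global maximum) are discarded; a map whose
global maximum is below 0.01 is declared empty.  Every cell of a flat
plateau that equals its window maximum is kept — a plateau yields
multiple detections by construction, which the oracle tests mirror.
Grid coordinates are mapped back to image scale by ×2.  At inference
D_mean comes from the size head ($d_p$); when evaluating against
annotated data it comes from the annotations.

**Sizing.**  Detected centers get KNN sizes by the same β/K rule
(fewer than K+1 detections: all available neighbours, with a warning;
fewer than 2: a configured fallback).  Because the KNN size blows up in
sparse regions, each size is capped by the regressed limit:
$D_j = \min(d_p, \bar d_j)$, the side of a square box centered on the
detection.

## Metrics

MAE and RMSE over per-image (truth, predicted-integral) counts, and a
coefficient of determination in two conventions: `standard`
(denominator $\sum (G_i-\bar G)^2$) and `as_printed` (denominator
$\sum (P_i-\bar G)^2$, spreading the predictions around the mean truth).
The two agree when prediction and truth spreads agree and differ
otherwise; both are reported, neither silently replaces the other.  Both
are invariant to adding a constant to both series.  The LNMS detection
count is reported alongside the integral count, never substituted for
it.

## Synthetic fields

The generator emulates what matters to this method: a near-regular grid
of plants (rows × columns with Gaussian positional jitter), each an
irregular rosette of 6–12 elongated green lobes whose intensity maximum
coincides with the annotated center; textured soil/water background with
low-frequency value noise, fine speckle and darker inter-row water
bands; occasional bright low-saturation glint patches (sun reflection on
paddy water) that exercise false-positive suppression.  Jittered
positions falling outside the image are rejected and logged.  Identical
specs (including seed) produce bit-identical images and annotations.

Default geometry is the scaled-down study condition: 256×256 tiles,
5×5 plants at 44 px spacing (jitter sd 3 px), radii 7–12 px — a dense
transplanted stand at reduced resolution.

It does **not** emulate: perspective or stitching geometry, occlusion
between plants, weeds, growth-stage variation, radiometric calibration,
or realistic leaf texture.  Passing recovery tests therefore show the
method's machinery is sound (targets, gradients, suppression,
localization and sizing logic), not field-readiness on real imagery.

## Scaled-down training conditions

All training experiments use the tiny preset on one CPU:

* **Gradient-flow overfit**: one 128×128 field (9 plants), batch 1,
  300 iterations — total loss must fall below 10% of its start.
* **End-to-end recovery**: 50 training fields (≈25 plants each), crops
  of 96 px, batch 3, 2,000 stage-1 iterations with best-checkpoint
  selection by validation MAE every 250 iterations; on held-out fields
  the relative count MAE must be ≤ 20% and localization recall ≥ 80%
  within a radius of D_mean/2.
* **Size recovery**: stage 2 on eight 160×160 constant-pseudo-size
  fields, 400 iterations — d_p must land within 1 px of D_mean.

Learning rates: 1e-3 for stage 1 and 1e-2 for stage 2 under the tiny
preset (the full-preset default is 1e-4, batch 3).  With Adam the
per-parameter step is ≈ the learning rate, so 1e-4 cannot move a
freshly initialized network appreciably within these iteration budgets;
the smaller network tolerates the larger steps, and stage 2 is a scalar
regression whose target (~35 px) sits far above the softplus origin.
The crop size (96) is chosen so a 2,000-iteration run fits comfortably
on one CPU; crops still contain several plants at the default spacing.

## Known limitations

* The positive–negative loss can cancel opposing errors by
  construction; it is kept as defined.
* Flat plateaus in the density map produce one detection per plateau
  cell; with continuous-valued predictions this is measure-zero.
* Localization precision is reported but not bounded by the recovery
  tests; an attention branch trained on few synthetic fields still
  passes some background texture.
* No pretrained encoder weights are bundled; random initialization is
  the supported offline path (a pretrained-backbone checkpoint can be
  loaded through the standard checkpoint mechanism if produced
  elsewhere).
* The `full` preset is implemented and shape-tested but not trained in
  the test suite; CPU training at VGG widths is impractical.
* Max-pool gradients split ties evenly rather than picking one winner;
  for continuous activations ties are measure-zero.
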