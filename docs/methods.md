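# Methods

## Overview

`cdbntrack` implements a discriminative appearance-model tracker for
single cells and objects in image sequences. Its appearance model is a
convolutional deep belief network (CDBN): two probabilistic max-pooling
convolutional restricted Boltzmann machines (CRBMs) topped by a fully
connected logistic layer and an output unit. The model is pretrained on
a generic labeled 32x32 patch corpus, transferred to the tracking task by
swapping the class head for a single target-vs-background unit, and then
updated online inside a particle filter as frames arrive.

## The CRBM and probabilistic max-pooling

A CRBM couples real-valued visible units `v` (an `n_v x n_v` patch,
possibly multi-channel) to `K` groups of binary hidden units `h^k`
through shared `n_w x n_w` filters `W^k`, with per-group hidden biases
`b_k` and a shared visible bias `c`:

    E(v, h) = 1/2 Σ v_ij²  −  Σ_k Σ_ij h_ij^k (W̃^k ∗ v)_ij
              −  Σ_k b_k Σ_ij h_ij^k  −  c Σ_ij v_ij,

subject to the probabilistic max-pooling constraint: in every `C x C`
block of each hidden group at most one unit may fire, and the pooling
unit `p_a^k` is on iff its block contains a firing unit. Conditioned on
`v` each block is an exact `(C²+1)`-way softmax over "which unit fires,
or none":

    P(h_ij^k = 1 | v) = exp(I_ij^k) / (1 + Σ_block exp(I^k)),
    P(p_a^k  = 0 | v) = 1            / (1 + Σ_block exp(I^k)),

with bottom-up input `I^k = (W̃^k ∗_valid v) + b_k` (the valid
convolution with the flipped filter, i.e. the cross-correlation with the
filter). Given `h`, visible units are Gaussian with unit variance and
mean `Σ_k W^k ∗_full h^k + c`. All block softmaxes are computed with a
per-block log-sum-exp shift, so the conditionals are invariant under any
constant shift of a block's inputs and immune to overflow. On CRBMs
small enough to enumerate, the implementation matches the exact
marginals of the Boltzmann distribution to better than 1e-8 (this is a
test).

### Training: CD-1 with a sparsity penalty

Layers are trained by contrastive divergence with one Gibbs
reconstruction: exact conditionals on the data (positive phase), one
block-categorical hidden sample, the Gaussian reconstruction mean, and
conditionals on the reconstruction (negative phase). Gradients are
averaged per hidden position so the learning rate does not depend on
patch geometry. The hidden layer is massively overcomplete, so a
sparsity penalty `λ (ρ − q_k)²` on each group's mean data activation
`q_k` (target `ρ`) is descended alongside; its gradient is applied to
`b_k` directly and to `W^k` through the mean receptive field. The
penalty weight defaults to `λ = 50` (relative to the per-position CD
gradient scale), which holds the trained mean activation within roughly
a factor of two of the target across the configurations we ship; the
trained activation is monotone-decreasing in `λ` (tested).

Defaults for the greedy stage: learning rate 0.05, momentum 0.5,
minibatch 64, Gaussian `σ = 0.01` filter initialization, zero biases.
Patches are standardized to zero mean and unit variance before entering
the first layer, matching the unit-variance Gaussian visible units of
the energy function.

### Stacking and inter-layer scaling

The deterministic pooled activation `P(p_a^k = 1 | v)` is passed upward
as the next stage's input. Because a sparse layer's pooled output has
mean and variance far from (0, 1), each layer's pooled output is
affinely rescaled to zero mean and unit variance, with the two scalars
frozen from the pretraining corpus (analogous to frozen normalization
statistics). Without this the second CRBM sees inputs two orders of
magnitude smaller than its energy function assumes and learns nothing
usable; with it, the same Gaussian-visible machinery applies unchanged
at every level. The scalars are stored in the model container and
applied identically at inference, so the forward pass stays pure.

## The CDBN head, pretraining, transfer, fine-tuning

The reference architecture maps a 32x32 patch through CRBM1 (12 filters,
5x5, pool 2), CRBM2 (288 filters, 7x7, pool 2, fully connected to all 12
input maps), a 192-unit logistic FC stage and a 10-way softmax output:
spatial chain 32 → 28 → 14 → 8 → 4. A "reduced" preset (8/32 filters,
FC 64) has the same topology at desk scale, and a "tiny" preset exists
for fast tests. With dense layer-2 connectivity and a dense FC stage the
full model has 1,056,804 parameters (`n_parameters_`); most of them sit
in FC3 (884,928) and the layer-2 filter bank (169,633).

Pretraining is greedy and layer-wise (each CRBM trained on the previous
stage's rescaled pooled output), followed by supervised training of the
FC head on the frozen features (softmax cross-entropy, SGD with
momentum 0.5, learning rate 0.1, 500 epochs by default).

Transfer keeps every CRBM and FC3 parameter bit-exactly and re-draws
only the output layer, now a single logistic unit whose activation in
(0, 1) is the tracking confidence. Fine-tuning is end-to-end gradient
descent through the whole stack: the forward pass treats the pooling
probabilities as deterministic differentiable activations, and the
backward pass uses the closed form d P(p=1)/d I_ij = P(h_ij=1)·P(p=0).
Analytic gradients match central finite differences to better than 1e-4
relative error (tested). Because online buffers are class-skewed, the
binary loss uses inverse-frequency class weighting by default; a config
switch can freeze the CRBM stages and update only the head.

Starting fine-tuning from a *pretrained* model matters: in a randomly
initialized stack the pooling softmaxes are nearly uniform and the
factor `P(h)·P(p=0)` ≈ 0.04 per layer starves the lower layers of
gradient. Transfer is what makes the one-unit head trainable in a few
hundred epochs.

## Particle-filter tracking

The state is a box `x_t = (x, y, w, h)`. Motion is a Gaussian random
walk `N(x_{t-1}, Σ)` with default
`Σ = diag(6², 6², (0.02 w₀)², (0.02 h₀)²)` pixels — a conventional
choice for this family of trackers; it is fully configurable. The
observation likelihood of a candidate box is the CDBN confidence of its
patch, cropped with bilinear resampling to 32x32 (boxes partially
outside the frame are clipped first) and standardized.

Per frame: propagate N particles (default 1,000), multiply weights by
likelihood and normalize, report the maximum-weight particle (ties to
the lowest index), and resample multinomially when the effective sample
size `1/Σ w_i²` drops below `N/2` — a monotone transform of the
weight-variance trigger, numerically stabler to threshold. Weights
multiply across frames between resampling events, as in sequential
importance sampling.

### The three positive-sample tiers

The online update draws positives from three sets with different
adaptation speeds:

* **ground truth** `s_g⁺` — the first-frame box plus four one-pixel
  jitters (5 patches), immutable for the whole run;
* **long term** `s_lt⁺` — a FIFO of per-frame best-state patches capped
  at `T = 25`;
* **short term** `s_t⁺` — the 10 highest-confidence particle patches of
  the current frame (distinct boxes only).

Negatives `s_t⁻` (default 100) are drawn from an annulus around the
estimate (center distance 0.5–2.0 times the box scale) with IoU < 0.3.
Every frame the model is fine-tuned on the union (500 epochs at the
defaults). The mix anchors the model to the ground truth while still
adapting, which is what resists drift: in the occlusion experiment below
the short-term-only ablation degrades measurably while the three-tier
update does not.

Loss-of-target is reported (not acted on): if the best confidence stays
below a floor (default 0.2) for 5 consecutive frames the frame record is
flagged and tracking continues.

## Synthetic data

`make_class_dataset` generates ten parametric texture families
(low-frequency gratings at three orientations, coarse checkerboard,
blob, ring, corner wedge, step edge, square frame, blob grid) with
per-sample phase/position jitter, amplitude jitter and additive noise;
optional channels carry a mild class tint. The families were chosen so
that class identity survives two layers of sparse pooling — early
variants with high-frequency gratings collapsed into a single "periodic
texture" class at the 4x4 top grid. A pixel-space nearest-centroid
classifier exceeds 60% accuracy on it (tested), and the reduced CDBN
pretrains past 80% training accuracy.

`make_sequence` renders a bright Gaussian blob ("cell", ground-truth box
= 3x its radius) moving over a uniform background, with optional
similar-appearance clutter blobs, a global temporal illumination ramp,
target intensity drift, additive Gaussian noise and a full-occlusion
window in which a distinct patch covers the target. Four presets at
320x240 ship: `linear-clean`, `illumination-ramp`, `occlusion-10`
(10-frame occlusion), and `cell-dense` (25 low-contrast clutter blobs;
frame std < 0.1 of full scale, tested). What the generator does *not*
emulate: textured cytoplasm, cell division and contact, focus drift,
camera noise statistics, and multi-target ambiguity — passing on these
sequences demonstrates the mechanics of the method, not performance on
real microscopy.

## Problem sizes used in the shipped experiments

The library defaults are the reference configuration (1,000 particles,
500 epochs per frame, full architecture). The shipped tests and the
acceptance script run the same code at sizes chosen for a single CPU:
the reduced architecture, 500 pretraining patches, 120–150 particles,
8–10 update epochs per frame, and 25–30 negatives per frame; the
occlusion ablation averages 5 seeds. These sizes are stated here as the
package's own experimental design; all of them are plain constructor
arguments.

## Numerical and design choices

* CD uses a single Gibbs step (CD-1); the reconstruction uses the
  Gaussian mean rather than a sample, the usual low-variance choice.
* All randomness flows through injected `numpy.random.Generator`
  objects; identical config + seed reproduces a run bit-for-bit
  (tested down to the results CSV).
* Degenerate inputs: constant patches standardize to all-zeros; boxes
  with no frame overlap are errors; propagated box sizes are floored at
  4 px so candidate boxes stay croppable; if every particle likelihood
  underflows, weights reset to uniform with a warning.
* Multi-channel pretraining data are handled by filters with a channel
  axis; for grayscale tracking the first-layer filters are averaged
  over channels at transfer time (`to_single_channel`).
* The model container is a single `.npz` with named arrays plus a JSON
  header (architecture, normalization scalars, provenance); round-trips
  are bit-exact (tested).
* Layer-2 connectivity is dense over all input maps. The grouped
  alternative (288 = 12 x 24) would cut parameters 12-fold; we ship the
  dense variant and document the resulting parameter count rather than
  targeting any particular total.
* The evaluation module follows the standard benchmark conventions:
  precision at a 20 px center-error threshold, and success AUC as the
  mean of the success rate over the 21-point IoU threshold grid with a
  strict `>` (so perfect overlap scores 20/21).

## Known limitations

* Per-frame fine-tuning at the reference 500 epochs is the dominant
  cost; the `update_every` and `freeze_features` switches trade
  adaptation speed for throughput.
* The tracker is single-target; multi-cell scenes are handled as
  independent single-cell runs and there is no data association.
* The sparsity equilibrium (and hence the reported mean activations)
  depends on the data distribution; the factor-of-two band around the
  target is what the default penalty weight guarantees empirically, not
  a theoretical bound.
* Scale estimation is weak: the random walk on (w, h) is mild and the
  synthetic targets keep constant size.
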