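# Methods

This note documents the model, the training protocol, the synthetic data,
and the numerical and design choices made where the architecture family
leaves room for interpretation. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Architecture

**Encoder.** `depth` stages of double convolution (3×3 conv → ReLU → 3×3
conv → ReLU → batch norm) with 2× max pooling between stages; channel
widths double from `base_width`. When `use_se` is on, a
Squeeze-and-Excitation block (global average pool → bottleneck perceptron,
ReLU then sigmoid → per-channel rescale) recalibrates each stage output
before it is used as a skip connection. The pooled deepest plane is the
Transformer's input.

**Transformer bottleneck.** The bottleneck plane is linearly patch-embedded
with learned 1D position embeddings and passed through `n_layers` pre-norm
self-attention layers (multi-head softmax(QKᵀ/√d_k)V, residual connections,
layer-norm, GELU MLP). Two token planes are supported: the default hybrid
mode tokenises the CNN bottleneck (patch size `patch_size / 2^depth`, so
the published 224-px/patch-16 configuration yields 14×14 = 196 tokens), and
an `image` mode tokenises the raw input plane. The transformed tokens are
reshaped to their grid (token *i* → cell `(i // w, i % w)`) and 1×1-projected
to the decoder's bottleneck width.

**Spatial coefficient map W_s.** A self-attention matrix has token×token
shape, not a spatial one, so a reduction is required to obtain the
single-channel map the decoder multiplies in. We use the only head-agnostic
scalar-per-token quantity expressible from the attention weights: the mean
attention each token *receives* (mean over heads and query rows, i.e. the
column mean of the final layer's attention), reshaped to the token grid,
min–max normalised to [0, 1], and bilinearly resampled to each decoder
resolution. Degenerate (constant) reductions — a single token, or exactly
uniform attention — fall back to an all-ones map, which makes the
multiplication a no-op rather than amplifying numerical noise. W_s is
treated as a coefficient, not a gradient path: backpropagation does not
flow through the attention-to-map reduction (the Transformer still receives
gradients through the token path). A full finite-difference check confirms
all other gradients are exact.

**Decoder.** A UNet++ lattice: node X(i,j) (level *i*, column *j* ≥ 1)
receives the concatenation of X(i,0..j−1) with the bilinearly upsampled
X(i+1,j−1); the level-`depth` predecessor is the Transformer grid output.
Every node applies a double convolution to its level width. With
`use_unetpp` off, only the outermost column is built and each node receives
the decoder node below it — exactly a plain UNet (verified bit-for-bit
against an independently wired forward pass in the tests).

**TLA placement.** The Three-Level Attention block replaces the plain
double conv at the outermost node of each level (one per level): attention
gate on the skip features (gating signal = the upsampled deeper decoder
feature; at the deepest level, the Transformer grid), concatenation with
the dense-lattice predecessors and the upsampled gating feature, channel
attention over the concatenation, double conv to the level width, and
elementwise multiplication by W_s resampled to that resolution. Inner dense
nodes use plain double convs to bound compute. The attention-gate
intermediate width is `min(C_x, C_z)`; all resampling is 2D bilinear.

**Heads.** A 1×1 main head on the final node; when `use_side_outputs` is
on, one 1×1 side head per outermost node, bilinearly upsampled to the input
size; aux heads on the intermediate top-row nodes X(0,1..depth−1). Side and
aux outputs exist for training-time deep supervision only; inference uses
the main head.

## Initialisation

Convolutions use He-normal initialisation, linear layers Xavier-uniform,
and every gate's final sigmoid bias starts at +3 ("open gates", coefficient
≈ 0.95). A randomly initialised closed gate multiplies features — and
therefore gradients — by ≈ 0.5 at every attention site, which measurably
slows early SGD progress; the open start makes the untrained network behave
like its gate-free counterpart, analogous to identity-biased residual
initialisation. All initialisation is driven by the model config's seed.

## Losses

- Cross-entropy: −(1/N) Σ_c Σ_i u_ic log y_ic, with predicted probabilities
  clamped to [1e-7, 1] inside the logarithm.
- Multiclass soft Dice: 1 − 2·Σ_c Σ_i u_ic y_ic / (Σ_c Σ_i u_ic + Σ_c Σ_i
  y_ic), smoothed with 1e-5 in numerator and denominator. The class sum
  includes the background, exactly as the formula runs over all C classes;
  the evaluation metrics, by contrast, never report background.
- Compound objective: λ₁·Dice + λ₂·CE with λ₁ = λ₂ = 0.5 by default.
- Deep supervision: the compound loss of each supervised output (softmaxed
  per output), combined as a weighted mean with uniform default weights.
  A mean (rather than a sum) keeps the objective's scale independent of the
  number of heads, so ablations with and without side outputs are
  comparable at the same learning rate.

## Metrics

Per-structure Dice is reported in percent; two empty masks score 100 by
convention. The Hausdorff distance is the exact (100th percentile)
symmetric maximum of directed boundary distances — boundary pixels are mask
pixels 4-adjacent to the outside — scaled by the per-axis pixel spacing.
No percentile variant (HD95) is applied, since the method family reports
plain "Hausdorff distance". If a structure is empty in prediction or truth
the distance is undefined: it is reported as NaN, excluded from case means
and counted in the report, never silently zeroed. Case reports average
structures (and slices, for stacks) unweighted; structures absent from the
ground truth are excluded. Argmax ties resolve to the lowest class index
for bit-reproducibility.

## Training protocol

SGD with momentum 0.9, initial learning rate 0.005, weight decay 1e-4, and
polynomial decay lr·(1 − t/T)^0.9 over all iterations; Adam, AdamW and
AdaDelta are selectable alternatives. Augmentation applies, each with
probability 0.5, a random flip (horizontal or vertical) and a rotation by a
multiple of 90° (optionally plus a small angle, with nearest-neighbour mask
resampling). Images are normalised per image to zero mean and unit variance
before entering the network — the standard practice for CT/ultrasound
segmentation, and necessary here because the raw phantom intensities
occupy a narrow sub-range of [0, 1]. The model scoring best on the
validation split is retained. Cross-validation partitions patient
identifiers (never individual images) into k seeded folds of near-equal
size, trains one model per fold, and reports per-fold best scores with
their mean and sample standard deviation. Every stochastic element —
initialisation, splits, shuffling, augmentation — is driven by explicit
seeds, and the NumPy backend is deterministic, so (seed, configs, dataset)
fully determine the history and checkpoint.

## Synthetic phantoms

The generator emulates the structure of the clinical segmentation problems
this architecture targets without any anatomy: `n_structures` rotated
ellipses with structure-specific intensity bands (contrast range split
evenly, so structures are distinguishable but neighbouring bands are
close), a dark background, and additive Gaussian noise (σ = 0.03 of the
intensity range by default). The ultrasound-like variant adds a Gaussian
boundary blur and multiplicative gamma-distributed speckle. Later
structures overwrite earlier ones where they overlap; placement is
rejection-sampled so no structure loses more than half its area to later
draws (unbounded occlusion produced degenerate slivers that no segmenter —
and no clinician — would call a structure), and every label is guaranteed
at least 20 visible pixels. Everything is determined by the spec's seed.

What the phantoms do *not* emulate: anatomical shape priors, CT Hounsfield
physics, true ultrasound wave propagation, inter-patient variability
structure, or 3D context. Passing tests on phantoms therefore demonstrate
that the architecture, losses, metrics and training loop are wired
correctly and can learn a multi-class, low-contrast segmentation task —
not that the model reaches clinical-grade accuracy on real data.

## The desk-scale learning benchmark

`smoke_benchmark(seed)` fixes the package's standard end-to-end check:
64 phantoms of 64×64 px with 3 structures; the desk-scale model (depth 2,
base width 24, Transformer hidden 64 / 2 layers / 4 heads / patch 4,
≈ 246k parameters); 10 epochs of single-sample SGD at the reference
hyperparameters with a 56/8 train/validation split. Width 24 is the
smallest width at which this benchmark trains reliably — width 8 collapses
to the background class and width 16 undertrains within 10 epochs — and
single-sample batches maximise the number of SGD updates the 10-epoch
budget allows (560), matching the classical description of SGD as
per-sample updates. The whole run takes on the order of two minutes on one
CPU. The outcome is stochastic across seeds (best-saved validation Dice
roughly in the high 70s to high 80s); for a fixed seed it is bit-exactly
reproducible. Unit tests elsewhere use an even smaller configuration
(width 8–16, 32-px inputs) chosen to exercise every code path cheaply, in
inference mode for determinism.

## Numerical choices

- Weights are float32 (memory-bandwidth bound on CPU); the autograd engine
  is dtype-generic and gradient checks run in float64.
- Batch norm uses batch statistics in training and running averages
  (momentum 0.1) in inference; unit tests run in inference mode.
- Channel-attention follows the equation form (MLP applied to each pooled
  vector, then added) rather than the prose paraphrase (add first, then
  MLP); the two differ only by MLP linearity and the equation is taken as
  normative.
- Channel-attention/SE reduction ratio defaults to 16 (the conventional
  value); inside the network the effective ratio is gcd(channels, ratio) so
  arbitrary concatenation widths remain valid, while the standalone blocks
  reject non-dividing ratios.
- Smoothing constants: 1e-5 in the Dice ratio, 1e-7 log-clamp, 1e-8 in the
  z-score denominator, 1e-5/1e-6 in the batch/layer-norm denominators.
- Max-pool gradient ties share the gradient equally; argmax prediction ties
  take the lowest class index.
- Bilinear resampling uses align-corners=false convex weights (rows sum to
  1), so resampled coefficient maps stay inside [0, 1].

## Known limitations

- W_s carries no gradient; architectures in this family typically
  backpropagate through the attention reduction. At desk scale the effect
  was not separable from noise (disabling TLA entirely changes the
  benchmark score by well under the seed-to-seed spread).
- The exact decoder nodes hosting TLA, and what the gate output is
  concatenated with, are under-determined in the published description;
  the choices above (outermost nodes; concatenation with predecessors and
  the upsampled deeper feature) follow standard decoder wiring.
- Training at the published scale (224-px inputs, ViT-Base bottleneck,
  150 epochs) is out of reach of a CPU-only backend; the package's claims
  are therefore about correctness and desk-scale learnability, not
  benchmark accuracy on Synapse/CAMUS-class datasets.
- 3D volumes are handled by slicing to 2D; there is no volumetric network.
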