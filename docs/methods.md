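# Methods

This note records the modelling choices behind `thyfuse`: the
architecture and its conventions, the synthetic phantom corpus and what
it can and cannot show, the training protocol, and the numerical
decisions that matter for reproducibility.

## Architecture

**Hybrid single-modal encoder.**  Each modality has an independent
branch.  The convolutional stage is an 18-layer-style residual network
(7×7/2 stem + 3×3/2 max-pool + four stages of basic blocks) truncated
before global pooling; with the default widths and 224×224 inputs it
emits a 512×7×7 feature map (total stride 32).  A learnable transposed
convolution (default kernel 4, stride 2, no padding: 7×7 → 16×16,
512 → 64 channels) bridges the map to the Transformer: the map is
flattened into tokens and a learnable position embedding is added once,
at the bridge, not per block.

**Token orientation.**  The fusion sequence has shape (C″+1) × H″W″,
which reads naturally as *channels as tokens*: C″ = 64 tokens whose
embedding dimension is the flattened spatial map H″W″ = 256.  That is
the default.  Because this is an unusual convention, the conventional
positions-as-tokens layout (H″W″ tokens of dimension C″) is available via
`EncoderConfig.token_orientation = "positions"`; all shape contracts are
parametric in the orientation.  The token dimension must divide by the
inter-modal head count, which constrains the bridge geometry (256 = 8·32
by default).

**Intra-modal Transformer.**  Four pre-norm blocks (x ← x + SA(LN(x));
x ← x + MLP(LN(x))) with *single-head* self-attention whose key dimension
is the full token dimension (one undivided projection), and a two-layer
MLP with GELU.  The MLP hidden width is 4× the token dimension at full
scale — the convention of the ViT design this follows; the paper-scale
default is kept configurable (`mlp_expansion`).

**Adaptive modality-weight generation.**  A three-linear-layer MLP with
ReLU on the concatenated *flattened* branch features (no pooling — the
gate sees the raw feature vectors), softmax over two outputs, so the
weights are always on the 1-simplex.  Default hidden widths 256 → 64.
The final layer is initialized with small random weights so an untrained
gate starts near (0.5, 0.5) while still passing gradient to all three
layers from the first step; the softmax temperature is 1 and the gate's
input is *not* detached, so the branches receive gradient through the
gate as well.

**Adaptive cross-modal encoder.**  The weighted sum of the two token
sequences is prepended with a zero-initialized learnable cls token (its
position-embedding slot is row 0), and refined by a stack of pre-norm
blocks with 8-head attention (per-head dim = D/8) whose head outputs are
concatenated and mixed by an output projection.  The inter-modal depth is
not pinned by the source design; it defaults to 4, mirroring the
intra-modal depth.  The final cls embedding is the case representation.

**Head and variants.**  The classifier head is LayerNorm + one linear map
to the two classes (the cls-token classification convention).  Ablation
variants that bypass the cross-modal encoder concatenate the flattened
branch features and fold them through a two-layer adapter (hidden 256,
output = token dimension) before the same head, keeping head capacity
comparable.  The pure-CNN branch keeps the convolutional encoder and the
bridge but no Transformer blocks; the pure-Transformer branch replaces
them with a ViT-style patch embedding producing the same (C″, D) token
geometry, so every variant shares the fusion interface.  The no-gate
variant fixes the weights at (0.5, 0.5).  Decision threshold: argmax
(0.5 on the malignant probability).

**Backbone initialization** is framework-default random (He for
convolutions, N(0, 0.02) for Transformer projections); no transfer
learning.  A `pretrained` flag exists in the config schema but no
pretrained weights are distributed with this package, so setting it is a
validation error rather than a silent fallback.

## The NumPy network core

No GPU framework is assumed: `thyfuse.nn` is a small reverse-mode
autodiff engine over float32 NumPy arrays.  Convolutions and their
gradients are lowered to BLAS matrix products through im2col
(`sliding_window_view`); the col2im scatter loops only over the k×k
kernel footprint.  Every backward pass is validated against central
finite differences in the test suite.  All computation is deterministic
for a fixed seed on a fixed platform, which is what makes the bytewise
run-reproducibility guarantee possible.

## Synthetic phantom corpus

The generator emulates the *structure* of a paired US/IRT cohort, not its
physics:

* **Ultrasound (512×512, values in [0,1]).**  Multiplicative
  Gamma-distributed speckle (shape 4, lightly smoothed) over a background
  of intensity 0.55; an elliptical nodule near the frame centre whose
  boundary radius is perturbed by a random 5-harmonic series with
  class-dependent amplitude.  Malignant cases draw higher boundary
  irregularity (0.12–0.30 vs 0.02–0.08 of the radius), taller-than-wide
  aspect ratios (1.05–1.60 vs 0.70–1.05) and lower echogenicity
  (0.40±0.08 vs 0.60±0.08).
* **Thermography (320×240, 20–40 °C).**  A left–right symmetric smooth
  neck field (ambient 31.5±0.4 °C plus a symmetric warm region of
  1–2.5 °C) with additive sensor noise (σ = 0.15 °C, matching a
  ~0.1 °C-resolution detector).  Malignant cases add a hotter
  (2.0–4.5 °C vs 0.3–1.2 °C), laterally displaced hotspot (asymmetry
  index 0.25–0.60 vs 0–0.08).  Temperatures are clipped to the sensor
  range and mapped through a fixed monotone pseudo-color map
  (R = t, G = t², B = (1−t)²), so temperature ordering survives into the
  red channel.
* **Informativeness control.**  Each case lists its informative
  modalities.  An *uninformative* channel draws its parameters from a
  class-neutral mid-range distribution (e.g. echogenicity 0.50±0.06,
  hotspot 1.0–2.2 °C) rather than from either class: it carries no label
  information, looks plausibly ambiguous, and — importantly — is in
  principle *recognizable* as non-diagnostic, which is what makes
  per-case modality weighting a learnable, measurable behaviour.  Had the
  neutral channel instead been drawn from the 50/50 mixture of the class
  distributions, it would display a convincing wrong-class phenotype half
  the time and the attainable multi-modal accuracy would provably
  collapse to the single-modal ceiling.
* **Split rule.**  Per class, validation and test sizes are
  ⌊0.2·N⌋ each and training takes the remainder; for class totals
  1536/1328 this yields exactly (922, 307, 307) and (798, 265, 265).

All distribution constants live in one frozen `PhantomParams` block so
tests can reference them.  What the phantoms do **not** emulate: acoustic
wave propagation, attenuation or shadowing, bio-heat transfer, anatomy,
probe or acquisition-protocol effects, and inter-observer label noise.
Passing tests therefore demonstrate that the architecture's mechanisms
work and that the training loop can exploit complementary modality
structure — they say nothing about clinical performance.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) with coupled L2 weight decay 5e-4,
batch 32, categorical cross-entropy, cosine learning-rate decay
lr(e) = lr_min + (lr_init − lr_min)(1 + cos πe/(E−1))/2 from 1e-3 to
1e-4.  Inputs are rendered to [0,1], bilinearly resized to the network
input size, and standardized per channel by training-partition mean/std.
Model selection keeps the best-validation-F1 checkpoint (the source
protocol does not state a selection rule; best-val-F1 is this package's
choice).  The full-scale default is 200 epochs at 224×224; the
**desk-scale** geometry used by the tests and examples is 96×96 inputs,
stage widths (8, 16, 24, 32), 16 tokens × 64 dims, depth-2 intra- and
inter-modal stacks, 4 heads, MLP expansion 2, and 25 epochs — sized so a
complete train/evaluate cycle takes about a minute per model on one CPU.

Randomness is funnelled through named sub-seeds (data, split, init,
shuffle) derived from the single top-level run seed, so any artifact of a
run is reproducible from its echoed configuration alone.

## Numerical choices and edge cases

* float32 throughout; LayerNorm/BatchNorm ε = 1e-5; softmax is
  max-shifted; cross-entropy clamps log arguments at 1e-12.
* Attention inputs are checked for non-finite values before the softmax
  and raise a numeric-validity error naming the stage; training aborts
  with the epoch index if the loss goes non-finite.
* Confusion-matrix ratios with zero denominators are reported as 0 and
  flagged (`MetricSet.undefined`) instead of raising or emitting NaN.
* A stratified split requires at least one case per partition per class
  (N ≥ 5 at 6:2:2); smaller classes raise a degenerate-split error.
* Nodule geometry is validated against the frame (centre ± semi-axes
  scaled by 1 + irregularity); out-of-frame specs are rejected before
  rendering.
* The thermogram's mirror-symmetry axis is the pixel-grid centre
  (w−1)/2, so a zero-asymmetry field is exactly equal to its mirror
  before noise.

## Known limitations

* The parameter counts of the full-scale variants depend on bridge and
  head dimensions that the source design leaves open; published
  complexity figures are treated as reference magnitudes, not targets.
* Training at the full 224×224 / 200-epoch configuration is possible but
  slow on one CPU; the package's empirical claims are made at desk scale.
* The gating network's learned weights are interpretable only in
  aggregate; no calibration of the output probabilities is attempted.
* Checkpoints store parameters, buffers, the resolved configuration and
  normalization statistics; optimizer state is not checkpointed, so
  "resume" re-uses a finished model rather than continuing mid-schedule.
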