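# Methods

## The segmentation network

The model is a U-shaped encoder–decoder over 48×48 multi-channel tiles
in which every feature-extraction step is windowed multi-head
self-attention rather than convolution. The 48×48 input size is chosen
for tissue microscopy: it spans a cell-scale neighbourhood, large enough
for local cytoarchitecture, small enough that a whole-section image must
be processed tile by tile.

**Patch embedding.** A depthwise separable convolution with kernel and
stride 4 maps each input channel through its own bank of
`filters_per_channel` (default 12) 4×4 kernels; outputs are concatenated
channel-wise, so the latent depth is C = 12 × n_channels (96 at the
8-channel default) and no cross-channel mixing happens at the input.
This respects the design premise that each biomarker channel carries an
independent stain-specific signal; the first cross-channel interactions
happen in attention. A bias and a layer norm follow.

**Attention.** Tokens on the 12×12 grid are partitioned into 6×6
windows; each window computes multi-head scaled dot-product attention
(scores scaled by the inverse square root of the per-head depth
C/h — the `full_depth` config option divides by C instead), with a
learned relative-position bias per head and a fused D→3D query/key/value
projection. Blocks come in pairs: the second block of a pair shifts the
window grid by `window_size // 2 = 3` tokens toroidally; token pairs
separated by the wrap boundary receive a −10⁹ pre-softmax offset so the
shift bridges window seams without attending across the image border.
When a grid fits inside one window (6×6 and 3×3 scales), the window
shrinks to the grid and the shift is disabled — a shifted partner would
attend to exactly the same token set.

**Scales.** Patch merging concatenates 2×2 token neighbourhoods (4d),
layer-normalises and linearly projects to 2d without bias; patch
expansion inverts this (bias-free d→2d projection, 2×2 rearrangement,
layer norm on d/2). With a 12×12 starting grid only two mergings are
possible (12→6→3), one fewer than the 224×224 original this adapts, so
the network has two encoder scales plus a bottleneck and exactly two
skip connections. Skips concatenate the encoder stage *input* at each
scale with the same-scale decoder features; a biased linear map fuses 2d
back to d. A final bias-free 16×-depth projection rearranges tokens back
to pixel resolution, and a bias-free per-pixel linear head emits class
logits.

**Frozen reference configuration.** `reference_config.yaml` pins:
stage depths (2, 2, 1) (bottleneck single block, see above), heads
(3, 6, 12), MLP ratio 4, qkv bias on, relative-position bias on, embed
bias + norm on, encoder-end and decoder-end layer norms. Under these
conventions the 11-class, 8-channel model has exactly 4,990,032
trainable parameters; the count is a pure function of the configuration
and is verified in the test suite. Under-specified details were resolved
by adopting the conventions of the published shifted-window U-Net
reference design wherever a choice existed; the single-block bottleneck
is the one place a paired stage was reduced, on the grounds that its
3×3 grid fits inside one window.

## Compute backend

Training and inference run on `mcswin.nn`, a small reverse-mode autodiff
engine over numpy arrays (batched matmul, softmax, layer norm, GELU,
gather, cyclic roll, fused softmax cross-entropy) with an AdamW
optimiser. Every operation's gradient is validated against central
finite differences in `tests/test_autodiff.py`. Computation is float32,
single-threaded deterministic: fixed seeds give bitwise-repeatable
training runs.

## Training protocol

Pre-training minimises mean per-pixel cross-entropy with AdamW
(default lr 1e-4, batch 32, no weight decay) over the tile set built
from one half of a labelled section: a vertical split at ⌊W/2⌋, tiles on
a 48-grid, tiles whose mean intensity over all channels falls strictly
below a darkness threshold (default 2% of the image maximum) discarded,
every remaining tile touching ≥1 labelled pixel kept, plus a seeded 10%
sample (without replacement, round-half-away-from-zero) of the remaining
tiles. Filtering precedes sampling.

Binary fine-tuning copies every non-head parameter of the multi-class
model exactly and re-initialises a 2-class head (seeded truncated
normal; optionally the background and region columns of the multi-class
head). Click patches are trained with uniform per-pixel labels — the
whole patch is "region" or "background", matching the label granularity
an expert supplies interactively — at default lr 1e-5 and an enforced
budget of ≤400 epochs per round. Edit rounds form
(previous ∪ additions) \ removals and resume from the current weights
rather than re-seeding; a flag on the estimator (`warm_start`) controls
resumption.

## Inference smoothing

`segment_image` zero-pads an image to the next 48-multiple, predicts
argmax label maps at all (48/f)² offsets of a stride f | 48, and takes
the per-pixel mode over the maps that cover each pixel (non-zero offsets
leave uncovered margins; offset (0,0) guarantees one vote everywhere).
Ties break to the smallest class index, making the result deterministic
and order-independent. f = 48 is bitwise identical to plain tiling;
smaller f smooths seams at proportionally higher cost. The printed
index set for the offsets is interpreted as m ∈ {0, …, 48/f − 1} with
offsets m·f, which yields the stated window count and the f = 48 limit.

## Evaluation

IoU is computed per region after binarisation (region of interest vs
everything else, other regions included in background). A region with
zero predicted area is flagged DNP and contributes 0 to mean IoU; an
empty ground-truth mask is an error. "Improved" means strictly greater
IoU. Aggregation uses full precision; rounding to 2 decimals happens
only at display. Report means are always computed from the per-region
values, never copied from a printed summary row.

## Synthetic phantoms

`generate_phantom` emulates the structure the sampling and training
stages assume: a dark frame (margin 48 px, mean below the darkness
threshold, so frame tiles are excluded from training), a bright tissue
interior with cell-like speckle (random dots, Gaussian-smoothed,
density 0.01/px), and blob-shaped regions rasterised from thresholded
smoothed noise with exact-area quantile cuts. With `mirror=True` the
left-half layout is reflected onto the right half, emulating the
bilateral symmetry that justifies train-left/test-right evaluation.
Three default regions probe the visibility taxonomy of real anatomy:

- class 1 *plain*: +0.35/+0.25 intensity offsets in two channels;
- class 2 *textured*: 3× speckle density at 1/3 amplitude (mean nearly
  preserved) plus small offsets in two other channels;
- class 3 *cryptic*: no offsets; speckle correlation length 2.5 px vs
  1.0 px, first-order moments matched to the surrounding tissue.

What the phantom does **not** model: microscope optics, channel
bleed-through, stitching artefacts, staining gradients, anatomical shape
priors. Passing the end-to-end tests therefore demonstrates that the
pipeline's mechanics (sampling, optimisation, seeding, smoothing,
scoring) work and that fine-tuning recovers regions a global model
misses — not that the reference model reaches any particular accuracy on
real tissue.

## Scaled-down end-to-end conditions

CPU-scale tests use the 480×480×8 phantom and a reduced-width
configuration (`compact_config`: 3 filters per channel → C = 24, heads
(2, 4, 8), MLP ratio 2, same topology). The frozen workflow is:
pre-train 100 epochs (lr 2e-3, batch 8) on the left-half tile set;
per region, 30 synthetic clicks (10 positive ≥90% inside, 20 negative
from the surroundings) on the right half; fine-tune 200 epochs
(lr 1e-3, batch 8) from the seeded binary model; score with f = 48
inference. Learning rates are scaled up from the full-size defaults to
suit the small network and short schedules. Across seeds this
consistently improves at least two of the three regions over the
binarised multi-class baseline, with the cryptic region the marginal
case — consistent with a region class that is near-invisible even in
texture.

## Numerical choices and edge cases

- Layer-norm epsilon 1e-5; GELU is the exact erf form.
- Initialisation: truncated normal (±2σ, σ = 0.02) for linear and
  embedding weights and position-bias tables; zero biases; unit norm
  gains. Build seed and shuffle seed are independent arguments.
- Background-filter boundary: a tile mean exactly equal to the threshold
  is kept (strict-less discard).
- Mode-vote tie: smallest label index, verified by exhaustive two-vote
  enumeration.
- Checkpoints embed the configuration as YAML plus its SHA-256; loading
  refuses a hash mismatch.
- Images smaller than one tile are rejected; non-multiples of 48 are
  padded with zeros for inference and cropped on output.

## Known limitations

- The phantom's regions are convex-ish blobs; thin fibre tracts and
  nested structures are not represented.
- The numpy backend is practical at reference width for inference and
  small-scale fine-tuning, but full-scale 1000-epoch pre-training of the
  4.99M-parameter model is an overnight CPU job; the package targets
  method correctness, not training throughput.
- Only constant learning rates are provided; no schedulers, no Dice
  loss (cross-entropy only), no probability-averaging ensemble of offset
  maps (the mode rule is the contract).
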