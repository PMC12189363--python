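# Methods

`cardioseg` segments the left-ventricular blood pool (LV) and the
myocardium (Myo) in short-axis cardiac MR slices: a three-class semantic
segmentation (background / LV / Myo) produced by an encoder–decoder
network, wrapped in the pre- and post-processing a complete pipeline needs.
This note documents the models and procedures, the parameters that matter,
and the choices made where the design was genuinely open.

## Image enhancement

Raw delayed-enhancement slices are low-contrast and noisy. Enhancement is
two fixed stages, in order:

1. **CLAHE** (contrast-limited adaptive histogram equalization). The image
   is partitioned into a `tile_grid` (default 8×8) of tiles; each tile's
   256-bin histogram is clipped at `clip_limit` (default 2.0) times the
   mean bin height, the clipped excess is redistributed uniformly, and the
   resulting CDF defines a per-tile intensity mapping. Per-pixel outputs
   bilinearly interpolate the four surrounding tile mappings, so tile
   seams are invisible. Clipping bounds the local contrast gain, which is
   what keeps noise amplification in homogeneous regions acceptable.
2. **Bilateral filter**. Each output pixel is the normalized average of
   its `diameter` (default 9) neighborhood weighted by a spatial Gaussian
   (`sigma_space`, pixels; default 75, i.e. effectively flat across the
   window) times a range Gaussian on intensity difference
   (`sigma_intensity`, gray levels). CLAHE raises noise along with
   contrast; the bilateral stage removes that noise while leaving tissue
   borders sharp, because averaging is suppressed across large intensity
   differences.

**Why `sigma_intensity` defaults to 30.** The range sigma must sit below
the inter-tissue contrast or the range term stops discriminating and the
filter degenerates into a plain Gaussian blur. After CLAHE, neighboring
tissue classes in these images differ by roughly 60–100 gray levels; with
`sigma_intensity = 30` the cross-edge weight is at most `exp(-2)` and the
filter denoises within tissue while preserving edges. We verified on the
phantom that with this default the enhanced image's interdecile range
increases over the raw input (the point of enhancement), whereas range
sigmas of ~75 — a convention inherited from color photography — shrink it
below the input.

Order of operations on real data: enhance on the native [0, 255] scale
(CLAHE is defined on 8-bit histograms), then resize to the network size
(bilinear for images, nearest-neighbor for masks so no label is ever
invented), then map linearly to [0, 1]. Enhancement is deterministic and
can be disabled wholesale (`EnhanceConfig(enabled=False)`) for the
no-enhancement ablation.

## Augmentation

The policy is deliberately conservative — cardiac anatomy must stay
plausible:

| component | probability | magnitude |
|---|---|---|
| horizontal flip | 0.5 | — |
| rotation | 0.3 | uniform ±5° |
| joint shift / zoom / rotation | 0.5 | shift ±3% of frame, zoom ±5%, rotation ±5° |
| brightness / contrast | 0.3 | ±5% each |

Each component fires independently. Both rotation events share the same
5° limit; when both fire a single angle is drawn within that limit, so
the total rotation never exceeds 5° (composing two draws could reach 10°,
which would leave the declared envelope). Geometry is applied identically
to image and mask — the mask with nearest-neighbor interpolation, so its
label set cannot grow — and intensity jitter touches the image only.
Borders exposed by rotation or shifting are filled with background (0)
rather than inventing tissue. Brightness/contrast is `img*(1+c) + b·range`
followed by clipping, with deltas read as fractions of the value range.

`expand_dataset` cycles the source pairs round-robin and draws an
independent transform per emitted pair, growing e.g. 235 source slices to
exactly 3000 training pairs; identity transforms occur naturally whenever
no component fires. A fixed policy seed reproduces the expansion exactly,
and the per-pair transform log can be saved for audit.

Augmentation is intended for the training subset only; validation and
test data stay untouched.

## Synthetic phantom

The phantom generator makes every downstream stage testable without any
download. A slice is a bright LV disk (intensity 180) inside a darker
myocardial annulus (140) on a dim background (90), all on [0, 255], with

* a smooth multiplicative bias field (quadratic polynomial, ±20%)
  mimicking coil shading,
* additive Gaussian noise (σ = 20),
* jittered center position (±5% of the frame).

The class means deliberately overlap under this noise — the raw phantom is
low-contrast, so the enhancement stage is consequential on synthetic data
too. A patient is a stack of 5–10 slices whose LV radius shrinks linearly
to 55% of its basal value at the apex, with a fixed wall thickness per
patient; patient streams are spawned independently from the cohort seed,
so cohorts are reproducible. The phantom does **not** model infarct or
no-reflow lesions, papillary muscles, trabeculation, k-space artifacts, or
through-plane effects. Passing phantom tests therefore demonstrates that
the pipeline is mechanically and statistically sound, not that it reaches
clinical accuracy on real delayed-enhancement images.

## Network

The model is an encoder–decoder with dense nested skip pathways:

* **Encoder** (default): a 50-layer split-attention residual network with
  deep 3-conv stem and average-pool downsampling. Each bottleneck's 3×3
  convolution expands channels into `radix` (default 2) splits per
  cardinal group (default cardinality 1); the splits are summed, globally
  pooled, squeezed through a bottleneck (reduction 4, floor 32), and a
  radix-softmax yields per-channel weights, summing to 1 across splits,
  that recombine them. With radix 1 the gate is a sigmoid. Stage channels
  are 3, 64, 256, 512, 1024, 2048 at strides 1–32.
* **Decoder**: the UNet++ triangular grid. Node `x_{d,l}` upsamples its
  deeper input ×2 (bilinear), concatenates all same-level predecessors
  plus the encoder skip, and applies two 3×3 conv+BN+ReLU blocks. First-row
  widths are `decoder_channels` (default 256/128/64/32/16); inner grid
  nodes carry the encoder skip width, the canonical channel bookkeeping
  for this decoder. Deep supervision is off — a single head.
* **Attention**: a channel squeeze-excitation (cSE) gate — global average
  pool, two 1×1 convolutions with ReLU then sigmoid, multiplicative
  rescaling — on both the concatenated input and the output of every
  decoder node. `scse` adds a parallel 1×1-conv spatial sigmoid gate,
  combined with the channel-gated map by elementwise maximum; `none`
  disables gates. These switches, together with the `resnet-34` and
  `plain` encoder variants, span the ablation grid.
* **Head**: one 3×3 convolution to 3 logit planes; softmax over channels.

Grayscale inputs are replicated to 3 channels to match the stem. In the
full configuration the network totals ≈ 53.0 M trainable parameters
(25.4 M encoder, 27.6 M decoder + attention + head), which
`scripts/acceptance.py` recomputes. No pretrained weights ship with the
package; initialization is random (see below) and `pretrained=True`
raises with a pointer to checkpoint loading.

### Numerical substrate

No GPU framework is used: `cardioseg.nn` is a compact reverse-mode
autodiff core on NumPy float32 arrays. Convolutions run through a
strided-slice im2col and stacked BLAS matmuls in both directions;
upsampling is realized as dense 1-D interpolation matrices applied per
axis, which makes its transpose (the gradient) exact. Gradients are
retained on intermediate activations after `backward()`, which is what
Grad-CAM reads. Evaluation-mode forward passes are deterministic; the
count-based metric path is computed in float64.

### Initialization

Convolution weights are uniform on ±1/√fan_in (the long-standing default
of mainstream deep-learning frameworks), BN gains 1 and biases 0. Batch
normalization makes the forward pass insensitive to the weight scale, but
the scale matters for optimization at small step budgets: Adam moves each
coordinate by at most ~lr per step, so after a few hundred steps weights
can only travel a fixed distance, and an initialization 2–3× larger takes
correspondingly longer to leave behind. On the scaled-down phantom run
below this init trains to useful accuracy where He-normal initialization
(std √(2/fan_in)) barely moves — a reminder that at short horizons the
init is part of the optimizer.

## Objective and metrics

Training minimizes the multiclass soft Dice loss

    Dice_c = (2 Σ_i p_ic g_ic + smooth) / (Σ_i p_ic + Σ_i g_ic + smooth + ε)
    loss   = 1 − (1/C) Σ_c Dice_c

with `smooth = 0`, `ε = 1e-7`, and the mean taken over all C = 3 classes
including background. The loss consumes softmax probabilities; evaluation
consumes argmax-hardened masks — the two uses of "Dice" are kept distinct.

Evaluation metrics come from per-class confusion counts: IoU, precision,
recall, Dice = 2PR/(P+R) (identical to F1 on pixel sets, an identity the
suite asserts bit-wise, along with Dice = 2·IoU/(1+IoU)). Means are
unweighted over the three classes, background included. Reported results
are macro-averaged across evaluation batches, as mean ± sample SD
(n−1 denominator; a single batch reports SD 0); pooled (micro) counts are
also available. Conventions for degenerate denominators: a class absent
from both masks scores 1.0 on every metric for that batch (perfect
agreement on absence; `absent_policy="skip"` instead drops it from the
mean), and a ratio that is 0/0 with the class present on one side scores 0.

## Training

Adam (lr 1e-4, batch 8) with seeded shuffling; defaults target the
full-scale protocol (100 epochs at 256×256). No schedule, weight decay, or
early stopping by default — all exist as config hooks. Per epoch the
history records training loss and train/val mean IoU / Dice / F1; the
weights with the best validation mean IoU are retained. The public
surface is a model/results pair: `CardiacSegmenter.fit()` returns a
`FitResult` with the history table, `evaluate()`, and a `summary()`.
Checkpoints store weights, BN running statistics and a config echo, and
round-trip bit-exactly.

### Scaled-down study conditions

The test suite trains the reduced configuration — `resnet-34` encoder,
halved decoder channels (128/64/32/16/8), no pretraining — on 200 phantom
slices at 64×64 for up to 10 epochs (stopping early once validation mean
IoU exceeds 0.95), evaluating on 50 held-out slices from unseen patients.
These sizes keep a from-scratch CPU run in the minutes range while still
exercising every architectural component; they are the package's chosen
desk-scale protocol, not a claim about clinical-scale accuracy. The
dominant residual error of such short from-scratch runs is a one-to-two
pixel boundary band around the thin myocardial annulus — boundary
sharpening is the slowest thing Dice-trained segmentation networks learn,
and at a fixed Adam step budget it is the part left unfinished. Longer
runs of the identical protocol continue to improve smoothly.

## Grad-CAM

For target class c, the scalar target is the sum of class-c logits over
the pixels predicted as class c (falling back to all pixels when the
class is never predicted; the all-pixel target is also selectable). The
chosen decoder layer's activations A_k are weighted by the spatial mean
of ∂target/∂A_k, combined as ReLU(Σ_k w_k A_k), bilinearly upsampled to
the input size, and min–max normalized to [0, 1] (an identically zero map
stays zero). The default layer is the final decoder node before the
head (`x_0_4`) — the deepest feature map at full resolution; any decoder
node can be named instead. Overlays alpha-composite per-class color
washes (LV red, Myo green by default) with per-pixel alpha proportional
to the CAM value.

## Known limitations

* The NumPy core is CPU-only and single-device; the full 53 M-parameter
  configuration is practical for instantiation and inference, but
  training it at 256×256 belongs on GPU hardware with a mainstream
  framework.
* The phantom's simplicity means phantom accuracy says nothing about
  performance on pathological myocardium (infarct/no-reflow), which the
  label-merging policy folds into Myo.
* Bilinear mask-free resizing of images uses no anti-aliasing filter, so
  extreme downscaling can alias; the intended pipeline resizes by modest
  factors.
* scSE's max-combination and the cSE placement (both ends of every
  decoder node) are declared conventions among several used in the
  literature; the ablation switches exist precisely so they can be
  compared.
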