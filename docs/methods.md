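# Methods

## The segmentation model

`scunet.model.SCUNet` is a serial dual encoder–decoder network for
multi-class semantic segmentation of single-channel images (background plus
three tumour classes by default). Two VGG16-style five-layer
encoder–decoder structures run in series:

1. **Encoder 1** turns the input (grayscale replicated onto three channels)
   into feature maps `feature1..feature5` at widths 64/128/256/512/512 and
   resolutions 512→256→128→64→32 (defaults), using a hybrid dilated
   convolution (HDC) group per layer and 2×2 max pooling between layers.
2. **Decoder 1** upsamples with stride-2 transposed convolutions,
   concatenates the same-layer encoder map, and applies two 3×3
   convolutions per stage, producing `up4..up1`; `up1` (64 channels, full
   resolution) is the input of the second structure.
3. **Encoder 2 / decoder 2** repeat the scheme, but every layer is
   additionally concatenated with the same-layer activation of the first
   structure and recovered to the layer width by two 3×3 convolutions
   (`feature7'..feature10'`→`feature7..feature10` on the encoder side,
   `up9'..up7'`→`up9..up7` on the decoder side). Layer 5 is the bottleneck:
   there is no `up5`/`up10`.
4. A 1×1 convolution and per-pixel softmax produce class probabilities.

Assumptions and fixed choices where the design was open:

* **Transposed-convolution kernel.** 4×4 with stride 2 and padding 1 by
  default (an exact ×2 upsample with uniform overlap); 3×3 (stride 2,
  padding 1, output padding 1) is available via `upconv_kernel=3`.
* **Decoder 1 has no segmentation head** and no auxiliary loss; its only
  consumer is encoder 2 plus the cross-network skips.
* **Initialisation.** He-uniform for all convolution weights
  (bound √(6/fan_in)), zero biases, BN γ=1/β=0. Construction is fully
  seeded, so a fixed seed yields a bit-identical network.
* **Batch normalisation.** Per-channel, trainable affine; training mode
  uses batch statistics and maintains running averages (momentum 0.1,
  unbiased variance); evaluation mode uses the running averages.

The whole network runs on `scunet.nn`, a compact reverse-mode autodiff
engine over numpy arrays (im2col convolutions with dilation, transposed
convolution, max pooling, fused batch norm, softmax, Adam). Every
primitive's gradient is verified against central finite differences in the
test suite.

## Hybrid dilated convolution

A dilated convolution with rate *l* samples the input on a grid spaced *l*
pixels apart. Stacking dilated convolutions whose rates share a common
factor leaves periodic holes in the receptive field ("gridding"). An HDC
group is a sequence of *n* units of [dilated conv → BN → ReLU] whose rate
sequence r₁..rₙ satisfies, with Mₙ = rₙ and

    M_i = max[ M_{i+1} − 2 r_i,  M_{i+1} − 2 (M_{i+1} − r_i),  r_i ],

the criterion M₂ ≤ K (kernel size) together with gcd(r₁..rₙ) ≤ 1. The
default schedule is K = 3 with rates (1, 2, 3) and size-preserving paddings
rᵢ·(K−1)/2; the alternative (2, 3, 4) with paddings (2, 3, 4) is provided
as a preset. `validate_schedule` exposes all Mᵢ so callers can apply
stricter rules, and `HDCGroup` refuses invalid schedules unless explicitly
overridden. The validator is checked exhaustively (all rate triples ≤ 6)
against a brute-force receptive-field coverage oracle: M₂ upper-bounds the
largest hole left by layers 2..n, and every valid schedule starting at rate
1 covers its receptive field with no hole at all.

## Loss

The training loss is the compound *focal Dice loss*

    L = ω₁ · FocalLoss + ω₂ · (DiceLoss)^γ · log(cosh(DiceLoss)),

with ω₁:ω₂ = 4:1 by default. Conventions (all exposed in `LossWeights`):

* **DiceLoss** = 1 − soft Dice with smoothing ε = 1e−6, averaged over the
  foreground classes, computed over the whole batch before the adaptive
  exponent is applied.
* **FocalLoss** = mean over pixels of −α_c (1−p_t)^γf · ln p_t with
  γf = 2, uniform α, and p_t clamped to [1e−7, 1].
* **γ = 1** for the adaptive exponent: the (DiceLoss)^γ factor grows with
  the batch Dice loss, so poorly segmented batches weight the log-cosh
  Dice term more strongly, and the factor decays as segmentation improves.

log cosh is evaluated in the numerically stable form
|x| + log1p(e^{−2|x|}) − log 2, with gradient tanh(x).

## Evaluation metrics

Overlap metrics derive from a (k+1)×(k+1) pixel confusion matrix
(row = truth, column = prediction): MIoU, MPA, mPrecision, mDice and
accuracy. Per-class means run over the classes present in truth or
prediction of the pair being scored; classes absent from both are skipped
(0/0 is undefined), a class absent from truth only contributes 0, and
`include_background=False` drops class 0 from the means (default:
included). Dataset-level scores are means of per-image metrics, which makes
aggregation permutation-invariant over images.

Boundary metrics operate on 4-connected class boundaries (a pixel of the
class with a 4-neighbour outside it; the image border counts as outside),
with Euclidean distances on the pixel grid scaled by a configurable pixel
spacing (default 1.0; physical spacing gives mm):

* **Hausdorff95** — max of the 95th percentiles of the two directed
  nearest-neighbour distance distributions. `percentile=100` gives the
  exact symmetric Hausdorff distance.
* **ASD** — mean distance from predicted-boundary pixels to the
  ground-truth boundary; one-directional (and therefore asymmetric) by
  definition, with an optional symmetric variant.

Nearest-neighbour queries use a KD-tree; the statistics are verified
against an all-pairs brute-force oracle in the tests.

## Synthetic phantoms

`scunet.phantoms` generates the test bed: a bright elliptical "head" with
smooth low-frequency texture (Gaussian-filtered noise, σ = 12 px) on a dark
field, 0–2 rotated elliptical lesions per image drawn uniformly over the
three classes, class-coded mean intensities (0.62 / 0.78 / 0.93 against a
~0.35 head base, per-lesion σ 0.03) so class identity is learnable from
appearance, and additive Gaussian pixel noise (σ 0.02) clipped to [0, 1].
Defaults emulate the study conditions: 512×512 images, semi-axes 10–50 px,
a 10:1 train/test split (remainder to train), and a label mask over
{0..3} colour-coded red/green/yellow for glioma/meningioma/pituitary.
A lesion pixel belongs to a lesion iff its centre satisfies the ellipse
inequality (skimage rasterisation); overlapping lesions resolve by draw
order (later wins); provenance (exact ellipse parameters per lesion) is
recorded alongside each phantom.

What the phantoms deliberately do **not** model: MRI physics (bias fields,
multi-modal contrast, partial-volume effects), anatomy beyond the head
ellipse, and non-elliptical lesion shapes. Passing tests on phantoms
demonstrates that the architecture, loss, optimiser and metrics are wired
correctly and that the network can fit structured image/label pairs — not
that it reaches any particular accuracy on clinical MRI. Optional
flip/rotation augmentation mirrors the idea of the study's image
enhancement but is off by default.

## Training

`train_model` runs Adam (β = 0.9/0.999, ε = 1e−8) on the compound loss
with the half-cosine schedule lr(t) = lr_min + ½(lr0 − lr_min)(1 + cos πt/T)
stepped per epoch. Defaults follow the full-scale recipe: 50 epochs,
lr0 = 1e−4, lr_min = 0, batch size 4. Data order is reshuffled each epoch
from the run seed; training is single-threaded deterministic, so one seed
reproduces identical weights. A non-finite loss aborts with the offending
batch indices. Checkpoints are numpy `.npz` archives with an embedded JSON
header (config + history); loading restores identical evaluation results.

### Capacity benchmark

`scunet.benchmarks.overfit_benchmark` is the standing end-to-end check: a
width-reduced network (widths 8/16/32/64/64) must overfit eight fixed
64×64 phantoms (1–2 lesions each, semi-axes 5–14 px) to training mDice
≥ 0.9 within 200 full-batch Adam steps of the 4:1 focal Dice loss. The
benchmark uses lr0 = 5e−3 annealed to lr_min = 1e−3: the full-scale 1e−4
is far too conservative for a 200-step budget, and annealing to zero
wastes the final steps, so the schedule keeps a floor. Problem sizes here
(8 images, 64×64, reduced widths) are chosen so the benchmark completes in
minutes on a single CPU core while still exercising every architectural
component; training mDice is read from the final epoch record, and the
run stops early once the target is reached.

## Numerical choices and degenerate inputs

* Dice ε = 1e−6 makes empty-class ratios 1, so an all-background exact
  match costs 0 and empty masks never divide by zero.
* Probabilities are clamped to ≥ 1e−7 before logs; clamping uses a
  straight-through-inside gradient (zero outside the clamp range).
* argmax prediction breaks probability ties toward the lower class index
  (numpy convention), i.e. toward background.
* `predict` reflection-pads images whose sides are not divisible by 16 and
  crops the result back.
* Boundary metrics raise on empty boundary sets, naming the empty side;
  `evaluate_pair` averages them over the foreground classes present in
  both masks and reports NaN when no class is shared (the dataset
  aggregator skips NaNs).
* 0-based (row, col) integer pixel coordinates throughout.

## Known limitations

* The engine is CPU/numpy: full-scale 512×512 training at widths 512 is
  far slower than a GPU framework; the package is sized for method study,
  not production training.
* Dataset-level boundary metrics are means of per-image class means, not
  pooled surface distances.
* The phantom generator's intensity-coded classes make class identity much
  easier than in clinical MRI; transfer of accuracy numbers is not implied.
* 2-D only; no volumetric convolutions or 3-D surface distances.
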