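# Methods

`hybridsi` implements a hybrid modeling framework for retinal neural
system identification in which a supervised encoding model and a
normative efficient-coding model are trained jointly through shared
convolutional filters, together with the synthetic data, preprocessing
and statistics needed to study the approach end to end on one CPU.

## The encoding (SI) models

The response of neuron *i* to a short stimulus clip is modeled as a
Poisson rate produced by a convolutional network. Two architectures are
provided:

* **Factorized (2D)**: one spatial convolutional layer (16 filters of
  9×9 per chromatic channel, no padding), one temporal convolutional
  layer (16×16×L, collapsing the L stimulus lags), flattening, one fully
  connected readout with per-neuron bias, and an exponential output.
  A 28×28 input yields 20×20 maps and a 16·20·20 = 6,400-dimensional
  readout input; a 36×32 movie frame yields 16·28·24 = 10,752.
* **Spatio-temporal (3D)**: one joint space-time convolution
  (16×2×L×9×9) followed by the same readout and exponential.

Training minimizes the Poisson deviance Σᵢ(r̂ᵢ − rᵢ log r̂ᵢ) plus L2
penalties on the convolutional filters (α₁ = α₂ = 10 for 2D; α = 100
for 3D) and an L1 penalty on the readout (β = 1/16 for 2D, 1/4 for 3D).
The readout bias is excluded from the L1 penalty. The spatial filters
may instead be composed from a fixed basis — the first k two-dimensional
DCT functions in JPEG zig-zag order ((0,0), (0,1), (1,0), (2,0), …), or
the top-k principal components of 9×9 channel-joint patches sampled
densely (stride 1) from an image corpus — in which case only the
16×k (PCA) or 16×k×2 (DCT) mixing weights are learned. These
basis-constrained models are low-pass-filtering controls.

## The efficient-coding (EC) branch

The EC branch is a convolutional autoencoder: same-padded 9×9
convolution (16 filters; a 2×28×28 image gives a 16×28×28 activation,
flattened to 12,544), ReLU, a fully connected encoder to the latent
vector h, ReLU; the decoder mirrors it (fully connected, ReLU,
transposed convolution, tanh to return to the [−1, 1] data range).
There is no hard bottleneck: capacity is limited by Gaussian noise added
to the encoder output during training (SD 0.1 in post-ReLU activation
units; off at evaluation) and an L1 penalty on h (β₂ = 1/16); L2
penalties on conv and deconv weights (α₃ = 10³) encourage smooth
filters. The 3D variants consume 8-frame clips: *past encoding*
reconstructs the clip's 7th frame; *future prediction* receives the
first 7 frames (the 8th input slot is filled with their per-channel
mean) and predicts the 8th. The 3D decoder always emits a single frame,
so its transposed convolution is 2D. The latent dimension defaults to
512 and is configurable.

The transposed convolution is implemented as a same-padded correlation
with the spatially flipped, channel-transposed kernel, which keeps
input and output sizes exactly equal.

## The hybrid objective

The two branches share one filter tensor (the SI spatial filters in 2D,
the joint filters in 3D) — the same parameter object, not a copy — and
are trained simultaneously on the weighted total loss

    L = w·L_SI + (1 − w)·L_EC,
    L_SI = (Poisson + α₁‖w_cs‖² + α₂‖w_ct‖²/w + β₁‖w_f‖₁/w) / N₁,
    L_EC = (MSE + α₃‖w_cs‖² + α₃‖w_d‖²/(1−w) + β₂‖h‖₁/(1−w)) / N₂,

with N₁ the neuron count and N₂ the number of images in the EC batch.
The /w and /(1−w) denominators keep the effective strength of
branch-private penalties constant as w varies, so w trades off only the
data terms and the shared-filter penalties. At w ∈ {0, 1} the weight is
substituted by 10⁻⁸ / 1 − 10⁻⁸ to avoid division by zero; the model
then behaves as the stand-alone EC or SI model. Two consequences of
this construction worth knowing:

* At w = 1 the gradients with respect to all SI parameters equal the
  stand-alone SI gradients (up to the 1/N₁ scale, to which Adam is
  insensitive), and the EC reconstruction term is suppressed by 10⁻⁸ —
  but the EC-private penalties stay at full strength by design, and the
  latent L1 reaches the shared filters through the encoder. The
  limiting-case equivalence is exact only with β₂ = 0.
* Duplicating the EC corpus leaves the per-image reconstruction loss
  unchanged; the penalty terms, being inside the /N₂ normalization,
  scale accordingly.

Optimization is adaptive-moment gradient descent (Adam) with one
gradient step per mini-batch pair: SI batches are contiguous 32-clip
blocks of training times, shuffled at the block level each epoch
(overlapping clips inside a block share stimulus frames, which the
forward pass exploits by convolving each frame once); EC batches of 32
images are drawn from an independently shuffled cycle. Validation
predictive correlation (single-trial) is evaluated every epoch;
training stops after 3 consecutive non-improving epochs (configurable)
or at the epoch cap, and the best-validation snapshot is restored.
When a data-efficiency run uses less than the full training segment,
the leading contiguous fraction is kept and the learning rate is
doubled, mirroring the training protocol for reduced data.

## Numerical core

PyTorch-class autodiff frameworks are deliberately not a dependency:
the models are a single convolutional layer plus affine maps, so the
package ships a small tape-based reverse-mode engine over NumPy arrays
(`hybridsi._autodiff`). Convolutions are evaluated in the Fourier
domain: with the FFT size equal to the padded input, circular
correlation equals linear correlation on the valid region, and the
kernel and input gradients are correlations of the same triple, so the
whole layer is batched FFTs plus small per-frequency contractions.
Training runs in float32; the loss-oracle tests run the identical code
in float64, where the FFT path agrees with brute-force summation to
~10⁻¹³ relative. Gradient checks against central differences cover
every primitive. Autoencoder biases initialize at +0.1: a ReLU unit
resting at exactly 0 receives no gradient, and zero-initialized biases
can leave the whole latent dead from the first step.

## Synthetic study conditions

No recordings ship with the package; the generators define the study
conditions and are treated as fixed:

* **Stimulus**: independent binary dense noise, ±1 with probability
  0.5 per pixel, frame and chromatic channel (UV, green), 28×28 at
  5 Hz. 2,400 non-test frames (480 s) split 440 s train / 40 s
  validation, plus a 50-frame (10 s) test sequence simulated with 6
  repeats.
* **Ground-truth neurons**: linear-nonlinear cells with
  difference-of-Gaussians spatial receptive fields (center σ ∈
  [1.0, 1.6] px, surround at 2σ with equal-volume scaling and weight
  0.4–0.7, random polarity), biphasic unit-norm temporal kernels over
  8 lags, and a softplus output nonlinearity (gain 2). Chromatic
  dominance follows retinal topography: "ventral" populations weight UV,
  "dorsal" green, with the non-dominant channel at 0.1–0.4.
* **Trial noise**: additive Gaussian on the rate (SD 1.0), clipped at
  zero — matching continuous, nonnegative Ca²⁺-derived event rates
  rather than Poisson spikes. This yields quality indices with median
  ≈ 0.6, comfortably above the QI > 0.25 inclusion threshold but far
  from noiseless.
* **EC corpora**: natural-like images are 1/f-spectrum Gaussian fields
  passed through a signed-square pointwise nonlinearity (x → x|x|),
  which adds sparse, heavy-tailed higher-order structure so that the
  structured vs phase-scrambled contrast is meaningful; channels share
  a common component (correlation 0.8); every image is normalized to
  RMS contrast 0.45 (clipped at [−1, 1]) — with much lower contrast
  the reconstruction term is dominated by the penalties and the
  autoencoder degenerates. Phase scrambling replaces Fourier phases
  with those of a white Gaussian field (Hermitian by construction, DC
  preserved; the RMS survives by Parseval, and only images pushed past
  the range are scaled down).
  White-noise corpora are binary ±1. The synthetic movie for the 3D
  variants evolves the Fourier coefficients as an AR(1) process with a
  global drift phase ramp — an approximation of footage dominated by
  global motion, not a model of real scenes.
* **Moving-bar trials**: 8 directions, a shared Gaussian temporal
  profile, von Mises direction tuning of strength s ∈ [0, 1], additive
  Gaussian trial noise.

What passing tests on these data do and do not show: they demonstrate
that the machinery is correct and that the hybrid regularization
behaves as described on data whose ground truth matches its inductive
bias (smooth, localized, center-surround filters). They cannot certify
effect sizes on real recordings, where nonlinearities, adaptation and
correlated noise are richer.

## Analysis

* **Receptive fields** are the gradient of a neuron's pre-exponential
  (log-rate) output with respect to the input at an all-zero stimulus —
  for these architectures the log-rate is linear in the input, so the
  gradient is exact everywhere; the log-rate is used rather than the
  rate to avoid an arbitrary scale. The [lags × (channels·pixels)]
  matricization is SVD-factorized; the temporal component is unit-norm
  with its largest-magnitude lag positive, and the spatial map absorbs
  polarity and magnitude.
* **Filter plausibility** is the R² of a least-squares elliptical
  Gaussian fit (amplitude, center, σx, σy, rotation, offset) to a
  spatial filter, initialized at the absolute peak with σ = 2 px and 5
  jittered restarts; R² is clipped to [0, 1], set to 0 for constant
  filters, and forced to 0 when max(σx, σy) exceeds the 9-px filter
  size. The metric is invariant to filter sign and scale. For 3D
  filters the spatial component is extracted by SVD first. Population
  summaries use each filter's dominant chromatic channel (largest peak
  absolute value; ties go to the lower index and are logged).
* **Predictive performance** is the Pearson correlation between the
  predicted rate trace and the repeat-averaged test response.
* **Direction selectivity**: the trial-mean [time × direction] matrix
  is SVD-factorized; the leading right-singular vector (sign-fixed to a
  nonnegative sum, clipped at zero) is the tuning curve, and the index
  is the normalized vector sum |Σ w_d e^{iθ_d}| / Σ w_d — 1 when all
  tuning mass sits in one direction, 0 for symmetric tuning. The
  normalization makes the one-direction response the strict maximum,
  which the raw (unit-norm-tuning) vector sum does not. The null
  distribution shuffles direction labels across trials (1,000
  permutations by default) and p-values use the add-one estimator
  (b+1)/(n+1), so they are never zero.
* **Model comparison**: paired two-sided sign-flip permutation test on
  the mean per-neuron score difference (10,000 resamples, add-one);
  uncertainty as 2.5/97.5 percentile bootstrap of the mean.

## Scaled experiment protocol

The experiment runner (`ExperimentSpec`) uses scaled-down defaults
chosen so that a full model-comparison grid runs in minutes on one CPU:
learning rate 10⁻³ with at most 40 epochs (patience 4), EC latent
dimension 256, and 20×20 EC images (the shared filters fix only the
channel count and kernel size, not the EC image size). The library
defaults (`HybridConfig`) keep the reference protocol instead —
learning rate 10⁻⁴, 100 epochs, latent 512, 28×28 — and were used to
verify that the scaled settings reach the same or better validation
optimum, only faster. The branch weight default w = 0.5 is the
validation-CC argmax over {0.3, 0.5, 0.7} under the scaled protocol
(at this learning rate smaller w leaves the response-prediction data
term too weak to train); `sweep` reproduces that selection explicitly.
The restricted-data model comparison runs on a 20×20 stimulus with 40
neurons and 30% of the training segment — where regularization matters
most — while receptive-field recovery keeps the full 28×28 / 50-neuron
conditions.

## Known limitations

* The LN ground truth is exactly within the model class (up to the
  softplus/exponential mismatch); real neurons are not.
* The gradient-RF estimator is exact here because the pre-exponential
  model is linear; for deeper nonlinear encoders it is only the
  first-order approximation at the expansion point.
* The synthetic movie's motion statistics are a rough stand-in; results
  for the 3D past/future variants should be read as machinery checks.
* Quality-index filtering, chirp-stimulus responses and functional cell
  typing beyond the DS/non-DS split are out of scope.
* The package is a library with example scripts rather than a shell
  tool: the importable API (`simulate → train → analyze → report`) is
  the supported interface, and `examples/` shows one narrative script
  per capability.
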