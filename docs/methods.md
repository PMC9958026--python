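# Methods

This note records the scientific and numerical choices behind the package:
what is modeled, which parameters matter, what the synthetic data do and do
not establish, and where the design was genuinely open.

## Problem setting

A single-cell Raman spectrum is an intensity vector sampled on a strictly
increasing wavenumber axis (cm⁻¹). Strain-level classification treats each
spectrum as one observation of one cell; acquisition artifacts (cosmic-ray
spikes, fluorescence background, arbitrary intensity scale) must be removed
before any classifier sees the data.

## Preprocessing

**Cosmic-ray removal.** Spikes are one-to-few-channel bursts, far sharper
than any Raman band. A channel is flagged when the robust z-score of its
second difference — (|d² − median|)/(1.4826·MAD), statistics taken over the
whole spectrum — exceeds `spike_zscore_threshold` (default 8). Because the
second difference of an isolated spike also fires on its neighbours, a
flagged channel is kept only if it is itself extreme against a local median
bridge (window `spike_window`, default 5 channels). Kept channels are
replaced by linear interpolation between the nearest unflagged neighbours.
Detection is single-spectrum; no replicate acquisitions are assumed. Note a
spectrum in which *every* channel is flagged cannot arise: MAD = 0 would
require at least half the deviations to be zero. The corresponding error
branch is defensive only.

**Baseline correction.** The fluorescence background is estimated by the
iterative modified polynomial fit (the standard reading of Raman toolbox
background-subtraction routines): fit a degree-`poly_degree` (default 5)
polynomial by least squares on a mean-centred, range-scaled axis; clip
intensities above the fit to the fit; refit, until the maximum pointwise
change of the fit falls below `poly_tol` (default 10⁻⁴, relative to
max |y|) or `poly_max_iter` (default 100) is reached. Non-convergence logs
a warning and returns the last iterate — with detector noise present the
fit keeps creeping into the noise floor at the ~10⁻⁴ level, which is
harmless for classification. The Vandermonde pseudoinverse is computed once
per call, so each iteration is two matrix–vector products. The clipped data
vector decreases pointwise monotonically across iterations; the fitted
polynomial itself is monotone only up to small local upticks (least-squares
hat matrices have negative entries), while its mean — equal to the
clipped-data mean because the design contains an intercept — is exactly
non-increasing. `corrected + baseline = input` holds to float round-off by
construction.

**Normalization.** Per-spectrum affine map onto `[norm_low, norm_high]`,
default [0, 1]. Per-spectrum (not global) scaling and the non-negative
default range follow the appearance of per-trace normalized spectra in this
field; the range is exposed for the [−1, 1] convention. A constant spectrum
has zero dynamic range and is rejected by name.

## Synthetic data

The generator emulates a balanced 8-strain, 500-spectra-per-strain
single-cell dataset on a 400–3200 cm⁻¹ axis at 1 cm⁻¹ (defaults; all
configurable). Each rendered spectrum is

    Σ_peaks A·γ²/((x−c)² + γ²) · jitter  +  polynomial baseline
                                         +  Gaussian noise  +  spikes

- **Lorentzian line shapes** (the natural Raman line shape), default
  half-width γ = 8 cm⁻¹, widths drawn 6–12 cm⁻¹ for class-specific bands.
- **Peak tables**: every class carries the carotenoid triplet
  1004/1157/1520 cm⁻¹ (amplitude 1); each class adds 3–6 bands drawn
  without replacement from a fixed list of common microbial Raman bands
  (including the 540 and 1380 cm⁻¹ bands that separate Gram types),
  amplitudes 0.4–1.5, with pairwise-distinct band sets guaranteed.
- **Per-spectrum amplitude jitter**: log-normal with σ = 0.1 (10 %
  cell-to-cell intensity variation).
- **Noise model**: white Gaussian noise σ = 0.05 on O(1) peak amplitudes
  (peak SNR ≈ 20, typical of a few-second single-cell acquisition); a
  random degree-≤3 polynomial baseline with constant term 0.5–2 —
  fluorescence comparable in size to the peaks; cosmic-ray spikes with
  Poisson rate 0.1 per spectrum, amplitude ≈ 50 × σ.
- **Randomness contract**: one root seed; every spectrum uses its own
  counter-keyed stream (`SeedSequence([seed, 1, index])`), so generation is
  order- and subset-independent and bitwise reproducible.
- **Ground truth**: clean signal, baseline, noise and spike components are
  stored per spectrum and reconstruct the output exactly.

The simulator claims statistical, not biochemical, fidelity: the real
strains' discriminative bands are unknown (the measured dataset is not
public). It omits instrument response, wavenumber calibration error and
Mie-scattering backgrounds. A green end-to-end test therefore establishes
that the pipeline implements the protocol correctly and can separate
classes whose spectra differ by realistic band structure under realistic
noise — not that any particular real-world accuracy would be attained.

## Transformer

ViT-style adaptation to 1D, on a small reverse-mode autodiff engine (no
deep-learning framework; attention, layer norm, GELU, convolution and
pooling are hand-differentiated primitives, verified by central
differences):

- patches of `patch_len` = 16 channels (the 1D analogue of 16-pixel ViT
  patches; the source architecture names no 1D tokenization), right
  zero-padding to a whole number of patches;
- learnable class token and learnable position embeddings (the cited ViT
  design; fixed sinusoidal encodings would be the alternative reading);
- pre-norm residual blocks with GELU feedforward (ViT convention; the
  published block diagram does not fix norm placement or activation);
- classification head: layer norm + linear on the class token, softmax.

Presets: `"paper"` = 12 blocks / 12 heads / d_model 768 (≈ 85 M parameters —
constructs and runs forward on CPU but is not trained in the tests);
`"scaled"` = 2 blocks / 4 heads / d_model 64 / d_ff 256, the configuration
used in all shipped benchmarks. Dropout 0.1 by default, disabled at
inference.

**Initialization.** Projection matrices are Xavier-scaled
(std = √(2/(fan_in+fan_out))); embeddings use std 0.02; the head is
zero-initialized, so an untrained model outputs exactly the uniform
distribution and the first optimizer step is pure logistic regression on
the class token. The fixed std 0.02 of large vision transformers was tried
first and leaves a width-64 model under-excited (many epochs at chance
before symmetry breaks); dimension-aware scaling removed that plateau.

**Training.** Mini-batch Adam at its published defaults (lr 10⁻³,
β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ — "default settings"), mean cross-entropy
from logits via log-sum-exp. Per epoch the training set is reshuffled and
validation accuracy recorded; the returned parameters are those of the best
validation epoch (earliest on ties). Epochs, batch size and learning rate
are not fixed by the source description and are config-exposed; shipped
benchmarks use 8–20 epochs and batch 16–32. All randomness (init, batch
order, dropout masks) derives from the configured seeds, so training is
bitwise reproducible.

**Prediction.** Argmax of softmax probabilities; exact ties resolve to the
lowest class index (NumPy argmax convention, asserted by test).

## Baselines

AlexNet-2012 and ResNet-18 with k×k → k kernel substitution (the published
comparison names no variant; these are the canonical layer counts).
AlexNet-1D uses adaptive average pooling to 6 positions before its
fully-connected stack, making parameter count independent of input length;
ResNet-1D uses batch normalization with running statistics (stored in the
checkpoint) and strided 1×1 projections on downsampling shortcuts. A
`width_multiplier` (1.0 = published widths, 0.25 = desk scale) scales all
channel counts. Both accept the same training loop, prediction function and
checkpoint format as the transformer. In all shipped comparisons the
baselines see the same preprocessed spectra as the transformer; whether the
original study fed them raw spectra is ambiguous, and no attempt is made to
guess.

## Evaluation protocol

`stratified_kfold` deals each class's shuffled indices round-robin into k
folds, so per-class fold sizes differ by at most one (exactly 100 per class
per fold at 500/class, k = 5). For each fold the remaining data are
re-split 80/20 per class (round-half-up), the model is trained fresh, and
the best-validation parameters are scored once on the held-out fold. A
leakage assertion (test ∩ train = test ∩ val = ∅) runs on every fold. Both
the mean over fold accuracies and the best fold are reported, since "average
accuracy" and best-of-five selection are both part of the protocol and the
published average's base is not stated.

ROC/AUC is one-vs-rest on the softmax columns. The curve comes from a
threshold sweep over unique scores; AUC is its trapezoidal integral, which
equals the rank statistic with half-credit for ties (verified against
exhaustive pair counting and against scikit-learn).

## Scale of the shipped benchmarks

A NumPy implementation of this transformer needs ≈ 0.1 s per spectrum per
epoch at the full 2801-channel grid, so the complete 8 × 500 fivefold
protocol is hours of single-CPU time. The shipped end-to-end benchmark
(tests and `scripts/acceptance.py`) therefore runs the same stated world at
desk scale — 4 cm⁻¹ grid (701 channels), 100 spectra per class, scaled
preset, 8 epochs — in about 1.5 CPU-minutes, with un-scaled thresholds
(fivefold mean accuracy ≥ 0.95, every per-class one-vs-rest AUC ≥ 0.97).
The determinism check repeats the full simulate → preprocess → crossval
chain twice at 3 classes × 20 spectra and requires identical serialized
metrics.

## Known limitations

- No GPU or multi-core kernels; paper-scale training is out of reach.
- Cosmic-ray detection can in principle clip an extremely sharp genuine
  band on a coarse grid; the 8-MAD default is conservative against this.
- The modified polynomial baseline biases slightly low under noise (it
  descends into the noise floor); irrelevant after min-max normalization.
- Only linear interpolation for regridding; no spline (monotone,
  artifact-free, sufficient for classification input).
- Vendor binary formats (SPC/WDF), hyperspectral maps and
  wavelength↔wavenumber conversion are out of scope.
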