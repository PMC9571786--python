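# Methods

## The classification problem

Cartilaginous bone tumors span benign enchondroma (E) and chondrosarcoma
grades G1–G3. The clinically decisive calls are (i) separating high-grade
disease (G2/G3, treated aggressively) from the rest and (ii) the subtle
E-vs-G1 distinction, which drives very different management. Because G3
lesions frequently contain G2 regions, G2 and G3 are collapsed into a
single G2G3 category throughout; the task is three-way: {E, G1, G2G3}.

The input is a raw Raman spectrum: intensity (arbitrary units) versus
Raman shift over 200–3400 cm⁻¹, including fluorescence baseline and the
Rayleigh-scattering tail — no baseline correction or artifact removal is
performed, by design.

## The cascade

1. Each spectrum is z-scored (per spectrum, population standard
   deviation) and passed to a small 1D CNN — one convolution
   (1 → 4 channels, kernel 6, valid, stride 1, ReLU), max-pool
   (kernel 3, stride 3), then fully connected layers 1024/256/128 with a
   batch-norm after each (before the activation) and a single sigmoid
   output: P(EG1). Probability ≥ 0.5 routes the spectrum onward; ties go
   to EG1 so confusion matrices are reproducible.
2. Spectra called EG1 are transformed with a continuous wavelet transform
   using a generalized Morse wavelet, synchrosqueezed, rendered as a
   224×224×3 JET-colored image, and classified E vs G1 by a 2D CNN.
3. G2G3 calls terminate at stage 1.

Per-class accuracies therefore combine multiplicatively:

    Acc_G2G3^f = Acc_G2G3^1
    Acc_E^f    = Acc_E^2 · Acc_EG1^1
    Acc_G1^f   = Acc_G1^2 · Acc_EG1^1
    Acc^f      = (n_E·Acc_E^f + n_G1·Acc_G1^f + n_G2G3·Acc_G2G3^f) / Σn

Printed percentages report integer correct counts over known class sizes
(e.g. 83.3 % of 24 = 20/24, 82.8 % of 99 = 82/99). The default
`fraction_counts` mode of `aggregate_final_accuracy` reconstructs the
nearest-integer counts at the *stage* level and multiplies exact
fractions; rounding only the final display. The alternative
`printed_products` mode multiplies the rounded percentages directly and
exists as a sensitivity check. Rounding the *final* per-class counts
instead of the stage counts is wrong: for the PCA+SVM pipeline column it
yields 66.2 % where the correct stage-count arithmetic gives 65.7 %.

## Wavelet front end

The transform is W(a,b) = (1/a) ∫ s(t) ψ*((t−b)/a) dt with the analytic
generalized Morse wavelet, Ψ(ω) ∝ ω^β e^(−ω^γ) for ω > 0 (zero
otherwise), peak-normalized to 2. Defaults γ = 3, β = 60 (the common
"gmw" convention); scales are log-spaced at `nv` voices per octave
(default 64), auto-spanning peak frequencies from the Nyquist rate down
to two cycles per signal. Each row is computed as a frequency-domain
product, `ifft(fft(s)·Ψ(a·ω))`; reflection padding suppresses wrap-around
edge artifacts (`boundary="periodic"` gives the exact circular
transform).

**Synchrosqueezing.** Instantaneous frequency is the phase transform
Im[(∂W/∂b)/W]/2π, with ∂W/∂b computed spectrally (iω multiplier). Each
coefficient moves, weighted by d(log a) = ln2/nv, to the nearest
log-spaced frequency bin (bins coincide with the scale grid's peak
frequencies). Reassignment only moves values between bins, so the
frequency marginal equals the d(log a)-weighted scale marginal exactly —
the quantity inversion integrates. A "total squared magnitude" is *not*
preserved by complex reassignment (coherent sums change energy), so
conservation is stated and tested on the marginal, where it is exact.

**Inversion.** For scale-axis scalograms the frame inversion is used:
the weighted scale marginal has spectrum X(ω)·C(ω), with coverage
C(ω) = Σ_a Ψ(aω) d(log a) flat over the analyzed band; dividing by C on
the covered band (threshold 0.25·max) and taking the real part recovers
the signal. For frequency-axis (synchrosqueezed) scalograms the classic
one-integral formula applies: sum bins, scale by 2/C with the scalar
admissibility constant C = ∫Ψ(u)/u du (closed form via the gamma
function). Inversion is exact to rounding for circular transforms of
band-limited signals; reflect-padded transforms round-trip approximately
with error concentrated at the edges. `project_to_band` provides the
band-limiting projection that makes the precondition concrete.

**Rendering.** Magnitude → scale-invariant log compression
log1p(K·m/max m)/log1p(K), K = 1000 (the raw dynamic range is dominated
by low-frequency baseline energy) → per-image min-max → the classic
piecewise-linear JET map (closed form, platform-identical; value 0 =
dark blue, value 1 = dark red) → bilinear resize to 224×224, high
frequencies on top. A constant scalogram renders as the value-0 color.

## Stage-2 classifier

The canonical deployment of the second stage is an ImageNet-pretrained
ResNet-18 fine-tuned at a very small learning rate. This package bundles
no pretrained weights; the stage trains compact residual networks from
scratch, preserving what matters downstream: 224×224×3 input, residual
blocks with batch norm, a 7×7 final feature map into global average
pooling, dropout p = 0.2 before the linear head, and the same optimizer
family. Backbones: `resnet_small` (16/16/32/64 channels, default),
`se_resnet_small` (adds squeeze-and-excitation channel attention),
`effnet_small` (narrower width-scaled variant). The configured 2D
learning rate 5e-7 is kept as the fine-tuning default for fidelity;
from-scratch training uses the `from_scratch_config` preset (lr 1e-3),
since no network trains from random initialization at 5e-7.

For two classes the loss is categorical cross-entropy over the two
logits, which is identical to binary cross-entropy on the logit
difference. Argmax ties resolve to the lowest class index.

## Training conventions

* Optimizer: Adam (β = 0.9/0.999, ε = 1e-8); stage 1 lr 1e-4, weight
  decay 0.01 (L2 added to the gradient, as in the common framework
  convention); batch sizes 32 (1D) and 64 (2D).
* A weighted random sampler draws every class with equal probability
  (weights ∝ inverse class frequency).
* 1D augmentations, drawn fresh per batch: additive Gaussian noise with
  σ = 0.05 × spectrum peak, and integer grid shifts uniform on [−5, 5]
  steps (≈ ±10 cm⁻¹ on the 2 cm⁻¹ grid), edge-value padded — zeros would
  fabricate band edges on z-scored spectra.
* 2D augmentations: random crop offsets up to 2 % of each axis
  (≤ 4 px), resize back to 224, per-image z-score, additive Gaussian
  noise σ = 0.1 on the normalized values, sharpness factor uniform on
  [0.8, 1.2] (blend against a 3×3 box blur). Noise is applied after the
  z-score; evaluation uses the z-score alone.
* Every stochastic component is driven by a numpy Generator seeded from
  one master seed (`derive_seeds`), so loss histories and reports
  reproduce bit-for-bit on one platform.

All layers, losses and the optimizer live in `ramangrade.nn`, a small
explicit-backpropagation engine written for this package; its gradients
are verified against central differences in the test suite.

## Shallow baselines

PCA (30 components, fit on training data only), SVM (RBF kernel, C = 1,
gamma = 1/(n_features·Var X), one-vs-one multi-class), LDA (SVD solver,
tolerance 1e-4 read as the rank threshold, no shrinkage) and an MLP
(hidden layers 256/64, ReLU, Adam), all via scikit-learn; plus the
stage-1 CNN architecture run directly as a three-class model. LDA is
exposed both with and without PCA. Degenerate all-constant features
predict the majority class rather than erroring.

## Synthetic cohorts

The clinical dataset (400 spectra, 10 patients) is not distributable, so
the simulator emulates its reported structure:

| ingredient | default | rationale |
|---|---|---|
| grid | 1601 pts, 200–3400 cm⁻¹ (2 cm⁻¹) | finer than the 5 cm⁻¹ FWHM resolution |
| line shape | Lorentzian, FWHM 12 cm⁻¹ | typical condensed-phase Raman width |
| collagen 728/830/1206, chondroitin 1380 | multipliers 1.0 / 0.65–0.60 / 0.35–0.30 (E/G1/G2G3) | matrix degradation with malignancy |
| hydroxyapatite 960 | 0.15 / 1.0 / 0.20 | G1 calcification |
| DNA/RNA surrogates 785, 1578 | 0.30 / 0.60 / 1.0 | proliferation; canonical nucleic-acid shifts (a simulator convention) |
| neutral bands 1660, 2940 | grade-independent | amide I and CH stretch keep spectra realistic |
| fluorescence | quadratic hump, amplitude 1.5/2.0/2.5 by grade, 10 % per-draw jitter | broad baseline |
| Rayleigh tail | 3·exp(−(ν−ν_min)/150) | low-wavenumber artifact |
| patient effects | log-normal amplitude σ = 0.15; grid offset σ = 1.5 cm⁻¹ | makes patient-wise splits genuinely harder |
| noise | σ = 0.03 per point | acquisition noise |
| counts | train 69/76/101, test 31/24/99 (E/G1/G2G3) | the study's split sizes |
| patients | 3 per class, one held out per class for test | one-patient-per-class-out design |

`band_contrast` interpolates every grade multiplier (and the baseline
amplitudes) toward their grade mean: contrast 1 is the default
separation, contrast 0 makes the grades generatively identical. Within
the G2G3 category patients alternate underlying G2/G3 grades.

What the simulator does **not** model: calibrated Raman cross-sections,
instrument response, cosmic-ray spikes, wavenumber-dependent noise,
intra-patient spatial heterogeneity, or any real G2-vs-G3 distinction.
Passing tests therefore demonstrate that the pipeline recovers planted,
patient-confounded band structure — not clinical performance.

## Problem sizes used by tests

The suite trains at reduced sizes chosen to leave wide margins: the
full-cohort recovery run uses 30 1D epochs, 20 2D epochs and 32 voices
per octave (stage-1 and three-class accuracies land at 100 % on the
default cohort against thresholds of 90 %/85 %); contrast-degradation and
saliency checks use ~40-image cohorts, 10–15 epochs and 16 voices. Unit
tests use a 401-point grid.

## Numerical choices and edge rules

* Constant spectra z-score to zeros with a `degenerate` flag instead of
  raising.
* Stage-1 probability ties (exactly 0.5) predict EG1; stage-2 logit ties
  predict the lower class index.
* The conv kernel "6" with pool "3/3" means valid convolution and
  non-overlapping pooling; minimum input length 8.
* Batch norm uses momentum 0.1 running statistics; evaluation mode never
  touches batch statistics.
* CAM maps are min-max normalized to [0,1]; the column-to-wavenumber
  mapping is proportional (column j of m covers the j-th m-th of the
  axis), an explicit convention since the 2D-to-1D correspondence is
  approximate. Overlays smooth with a Gaussian (σ = 2 px) after bilinear
  upsampling; the interval threshold defaults to 0.6.
* Per-image render normalization couples local band changes to global
  image scale; planted-feature saliency tests therefore plant a band
  weaker than the shared structure so the normalization anchor is
  class-shared.

## Known limitations

* No pretrained backbones: absolute stage-2 accuracy on small cohorts is
  below what ImageNet transfer would give; the package's claims are about
  pipeline behavior on synthetic cohorts, not clinical accuracy.
* The numpy engine is single-threaded BLAS-bound; full-size cohorts with
  hundreds of epochs are out of its intended scope.
* Synchrosqueezed scalograms are inverted with the one-integral formula
  (scalar constant); accuracy degrades for signals near the edges of the
  analyzed band.
* G2-vs-G3 sub-classification is intentionally out of scope.
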