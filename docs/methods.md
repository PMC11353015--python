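# Methods

## Imaging model

A surface plasmon microscopy (SPM) image of point-like surface-bound
scatterers is modelled as the squared modulus of a sum of in-plane complex
fields sampled at pixel centres:

    I(r) = | E0 · e^{i k_sp (r·d̂)} + Σ_j A_j · e^{i (k_sp ρ_j + φ_j)} · e^{-ρ_j/L} / √ρ_j |²

with `k_sp = 2π/λ_sp` the surface-plasmon wavenumber, `d̂` the unit
propagation direction of the plane SP wave, `ρ_j = |r − r0_j|` the in-plane
distance to particle *j*, `L` the 1/e amplitude decay length of the
scattered wave, and `A_j`, `φ_j` the particle's scattering amplitude and
phase. The cross term between the plane wave and each scattered wave
carries phase `k_sp(ρ − (r − r0)·d̂)`, whose level sets are parabolas
focused on the particle — the characteristic parabolic fringe tail, which
extends along `+d̂` (the stationary-phase side).

Assumptions: scalar fields; a single propagating SP mode; pure in-plane
2-D propagation (the "decaying spherical wave" seen by the camera is
treated as a cylindrical wave with a `1/√ρ` geometric factor times an
exponential propagation loss — the simplest form that reproduces the
observed fringe geometry); linear superposition of scatterer fields (no
multiple scattering); no objective pupil, no leakage-radiation PSF, no
Fresnel stack for the metal film.

**Singularity clamp.** `1/√ρ` diverges at the particle. All radial factors
(envelope, loss, and the propagating phase inside the clamp disk) use
`ρ' = max(ρ, min_distance)`; outside the disk `ρ' = ρ`, so the clamp is
invisible beyond one pixel. Default `min_distance = pixel_pitch`.

**Coordinates.** Row-major pixel grid, origin at the centre of pixel
(0, 0), `x` grows with column index, positions are continuous (sub-pixel)
and expressed in µm. Scenes serialize losslessly to JSON with explicit
unit annotations.

### Default optical parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `sp_wavelength` | 0.6 | µm | visible-light SP wavelength scale |
| `decay_length` | 10 | µm | typical SP propagation length on gold |
| `pixel_pitch` | 0.1 | µm/px | diffraction-limited sampling (6 px per fringe) |
| `background_amplitude` | 1 | – | intensity normalization is per-image anyway |
| `image_shape` | 64 × 64 | px | desk-scale grid, 6.4 µm field of view |
| `min_distance` | 0.1 | µm | = pixel pitch; clamps the point singularity |
| amplitude range | [0.2, 1.0] | – | order-of-magnitude spread of particle cross-sections |

These scales are configurable; every reported result is a function of them.
Note that `decay_length` exceeds the default field of view, so tails span
the whole image and scenes with many particles are strongly overlapped —
counting is intentionally hard in the crowded regime.

## Degradation model

Blur, then noise:

1. **Disk blur.** Correlation with a radius-1 disk ("pillbox") kernel whose
   entries are the overlap areas between the disk and each pixel square
   (computed by 256× sub-pixel supersampling, normalized to sum 1), applied
   with replicate boundary handling. A constant image is an exact fixed
   point.
2. **Gaussian noise at a target SNR.** `SNR(dB) = 10·log10(P_s/σ²)` with
   `P_s` the **variance** of the clean (post-blur) image about its mean.
   Variance rather than mean square is used because the flat plasmonic
   background otherwise dominates the signal term and makes nominally
   harsh SNRs visually clean. The output is not clipped.

The order is fixed as blur→noise so the requested SNR is exact at the
output; the policy (`pipeline_order`, `signal_power_policy`) is recorded in
every dataset sidecar.

**Blank images.** A zero-particle clean image is constant, so its own
variance cannot scale the noise. The builder computes a per-configuration
*reference signal power* — the mean variance of a seeded batch of 20
blurred single-particle renders — and uses it for blank images only.
Physically: the noise floor belongs to the instrument, not to the particle
count. `add_noise` itself still raises on a constant image unless this
override is supplied explicitly.

## Synthetic training data

Three generation methods per class (labels 0–9 plus an "others" class for
N > 9, i.e. `label = min(n, 10)`; the others generator draws
`n ∈ {10,…,14}` uniformly):

* **M1 — pure simulation**: random scenes (uniform positions in a 4-px
  margin inset, uniform amplitudes and phases) rendered and degraded over
  the seven-condition grid {noise-free, 30, 25, 20, 15, 8, 1 dB}.
* **M2 — simulation on background**: the zero-mean interference term
  (render − E0²) is added to a background image, then degraded. With a flat
  unit background M2 reduces exactly to M1.
* **M3 — patch compositing**: single-particle crops (rendered at 30 dB,
  centred on the particle) pasted at uniform random positions by adding
  (patch − patch-border-mean); overlaps accumulate. M3 images are not
  re-degraded by default (patches carry their own noise); flag-switchable.

Backgrounds are synthesized as 1 + planar illumination gradient +
band-limited Gaussian speckle (Gaussian filter σ = ℓ/2 gives an
autocovariance with 1/e width ℓ) + 1-D streaks emulating vibration motion
artifacts. The background and patch generators are interface stand-ins for
crops from real measurements: a drop-in replacement with experimental
images requires no other code change (the default library size, 300
backgrounds, mirrors typical practice).

What the generator does **not** emulate: vectorial/polarization effects,
objective NA and aberrations, shot noise and detector gain, focus drift,
particle size polydispersity, aggregation, and the spatial nonstationarity
of real backgrounds. Tests passing on this data therefore validate the
pipeline's internal consistency and the learnability of counting under the
stated degradation model — not performance on real microscope images.

Default per-class budget: 7000 (M1: 1000 × 7 conditions) + 1000 (M2) +
100 (M3) = 8100, 11 classes, with per-class stratified 8:1:1
train/val/test split (floor for val/test, remainder to train:
6480/810/810). All per-image seeds derive from one master seed via
`numpy.random.SeedSequence`, so manifests rebuild bit-identically and
images pixel-identically. PNG output is per-image min–max quantized to
8 bits (a span at float-rounding level counts as constant and maps to
mid-gray 128), bilinear-resized to 224 × 224, and replicated to three
channels.

## Classifier

Two profiles share one training/prediction code path on a NumPy
neural-network engine written for this package (im2col convolutions,
depthwise convolutions, batch normalization, squeeze-and-excitation, Adam,
softmax cross-entropy; analytic backward passes pinned by
finite-difference gradient checks):

* **b0** (224 × 224 × 3): the nine-stage EfficientNet-B0 topology — 3×3
  stem (stride 2), seven MBConv stages alternating 3×3 and 5×5 depthwise
  kernels with SE ratio 0.25 of block input channels, then 1×1 conv →
  global average pooling → 11-way head. With the head widened to the
  canonical 1000 classes the parameter count is 5,288,548, matching the
  published topology; with the 11-class head it is ~4.02 M.
* **desk** (64 × 64): three conv(3×3)/BN/ReLU/maxpool blocks (8→16→48
  channels), global average pooling, dense 48→96→11; ~12 k parameters.
  Exists because full b0 training on ~90 k images is a cluster job, not a
  desk one; every bundled experiment runs the desk profile through the
  identical code path.

Inputs are standardized per image (zero mean, unit variance, σ floored at
1e-9 so blanks map to near-zero tensors) and replicated to three channels.
Networks train in single precision. Training hyperparameters (unstated in
the source study, so fixed here as package defaults): Adam, lr 1e-3 with
cosine decay, batch 64, 30 epochs, no augmentation (the optional
augmentation flag enables reflection across the propagation axis, which is
an exact symmetry of the imaging model). The checkpoint with the best
validation accuracy is returned (first epoch wins ties). No pretraining:
the ambiguity between fine-tuning and from-scratch training is resolved as
from-scratch, since no pretrained weights exist for this engine; the
config flag records the mode.

Prediction returns 11-way softmax probabilities; the label is the argmax
with the lowest-index tie-break. Run-to-run determinism holds for a fixed
seed on a fixed platform (BLAS reduction order can differ across builds).

## Evaluation

* **Confusion matrix**: counts then row normalization by row support;
  zero-support rows are flagged and left unscaled. Per-class accuracy is
  the diagonal.
* **Noise sweep**: fresh Method-1 test cells per (class, condition), plus
  the pooled "mixed" curve.
* **Peak-counting baseline** (the classical non-learned alternative):
  disk-smooth, subtract the median, count local maxima above k·MAD
  (default k = 6) with a 4-px minimum separation. It recovers isolated
  bright particles exactly and collapses once tails overlap — random
  scattering phases also hide particles with dark centres from a
  maxima-only detector.
* **Comparisons**: paired bootstrap (500 resamples, seeded); an inequality
  is asserted when the one-sided 95% lower bound of the accuracy
  difference is ≥ 0.
* **Timing**: mean wall-clock inference per image is reported as metadata
  only; it is hardware-dependent.

## Bundled desk-scale experiment

`spmcount.experiments.run_desk_experiment` generates a reduced
Method-1-only dataset — 72 images per class per noise condition
(504/class, the reduced counterpart of the full 1000 × 7), 64 × 64 native
grid — splits 8:1:1, trains the desk profile for 15 epochs, and evaluates
on the held-out test split (550 images). This is the package's chosen
desk-scale problem size; at it, the blank class (N = 0) and the "others"
class are recognized perfectly while accuracy decays with particle number
through the crowded mid-range, reproducing the qualitative shape of the
full-scale result at roughly half the overall accuracy.

## Numerical choices

* Disk-kernel construction: 256× supersampling; entries renormalized to
  sum exactly 1 (normalization tolerance 1e-12).
* Clamp disk: phase and envelope both use `ρ'` inside the disk, making the
  field constant there (no gradient artifacts at the centre pixel).
* Constant-image detection (quantization, baseline thresholds) uses
  relative tolerances ~1e-9 against float-rounding ripple.
* Split rounding: floor for val/test, remainder to train; classes smaller
  than 10 records are rejected rather than silently unsplit.
* `measure_snr` returns +∞ when the residual is exactly zero.
* Bootstrap ties: a tie yields a lower bound of exactly 0, which counts as
  "not worse".

## Known limitations

* Desk-scale mid-range accuracy (N = 3–9) is far below the full-scale
  figures; only the blank- and others-class behaviour is expected to match
  at this problem size. The N = 9 headline requires full-scale b0
  training.
* The scattered-wave form is a modelling choice; absolute intensities are
  not radiometrically meaningful (only contrasts matter after per-image
  normalization).
* The engine is CPU-bound NumPy; b0 training at full scale is out of its
  intended envelope.
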