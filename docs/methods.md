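# Methods

This note records the physical model, the numerical conventions, the
network and training protocol, and the design choices made where the
published description left the design open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Optical model

Scalar, monochromatic, coherent optics. Fields are complex amplitudes
sampled on a square grid (pixel pitch in meters); all elements are thin:

* **Sources.** Laguerre-Gaussian modes are launched at their waist, where
  the wavefront is flat and the Gouy phase zero, with profile
  `(√2 r/w)^|l| L_p^{|l|}(2r²/w²) exp(−r²/w²) exp(−i l φ)`. The printed
  form of this expression elsewhere carries a divergent `exp(+r²/w²)`
  envelope; the decaying envelope is implemented as the physically
  meaningful reading. The mode normalisation constant is fixed by requiring
  the *grid* power (Σ|U|²·pitch²) to equal the requested beam power
  exactly, after verifying analytically that the grid captures at least
  `min_capture` of the true mode power (below).
* **Propagation.** Band-limited angular-spectrum transfer function
  `H(f) = exp(i z √(k² − 4π²|f|²))` with evanescent components zeroed; this
  is the spectral half of a split-step scheme, and thin elements
  (object, diffuser) interleave as pure phase multiplications. Free-space
  legs are unitary on the propagating band, so power is conserved to
  rounding; the FFT's periodic boundary means energy walking off the grid
  re-enters on the far side, and a warning is emitted when the occupied
  bandwidth would walk further than half the grid.
* **Quantum numbers.** Modes are indexed by topological charge l ≥ 0 and
  radial order p ≥ 0 (p = 0 throughout the study conditions), with
  n = p + l, m = p, so n − m = l and n + m = 2p + l.
* **Matched Gaussians.** The comparison arm replaces each LG mode with a
  fundamental Gaussian of waist w₀√(1+l), the LG mode's effective spot
  size.

**Grid convention.** Square grids with even side; the optical axis sits at
index n//2 (the FFT origin), so the axis is a sample point — vortex cores
are exactly dark and Gaussian peaks land on a pixel. Fields are sampled at
pixel centers; the forward FFT sign is exp(−i k x).

**Grid capture.** A beam wider than the grid would silently lose power, so
generation compares the grid power against the closed-form mode power
(πw²/2 · (p+l)!/p! for the unnormalised envelope) and raises if the captured
fraction falls below `min_capture`. The default is 0.98: the nominal source
(w₀ = 0.63 mm on the 3.30 mm detector grid) captures ≈ 99.99%, and reading
the stated 1.26 mm spot size as a waist radius still constructs (≈ 98.2%).
The full-scale *Gaussian-arm* preset lowers `min_capture` to 0.95 because
its largest matched beam (w₀√5 ≈ 1.41 mm) captures only ≈ 96% of its power
on that detector — an intrinsic property of the published geometry, kept
rather than resized.

## Scene and acquisition

* **Phase objects.** 8-bit grayscale images map linearly onto phase,
  `φ = pixel/256 · 2π`, so 0 → 0, 128 → π and 255 → 2π·255/256. Dividing by
  256 rather than 255 keeps the map injective: mapping 255 to a full 2π
  would wrap the brightest pixels back onto the darkest. The (reflective)
  object is modelled as a transmissive phase mask — equivalent under the
  scalar model.
* **Diffuser.** A single thin random phase screen: white Gaussian noise
  smoothed by a Gaussian kernel of σ = L/2, rescaled to the requested phase
  standard deviation, wrapped to [0, 2π) on application. With that σ the
  screen's autocorrelation is Gaussian and falls to 1/e at lag L, the
  declared correlation length; the generator stores the unwrapped field so
  the statistic remains measurable at any strength. Defaults L = 15 µm and
  std = 2π (fully developed scattering) stand in for a grit-220 ground
  glass. The volumetric character of a real 2 mm diffuser (several mean
  free paths thick) is *not* modelled; one seeded realisation is shared
  across a whole dataset, like one physical diffuser.
* **Geometry.** The single stated propagation distance, 2 cm, is used for
  both legs (object → diffuser and diffuser → detector), matching a
  detector placed as close to the diffuser as the bench allows. Both legs
  are config-exposed.
* **Acquisition.** One intensity image per mode; channel order is l = 0, 2,
  4 (the l = 0 channel is identical in both arms by construction). The
  detector is ideal — no photon noise, no quantisation — so differences
  between arms reflect the illumination structure, not a noise model.
  Downsampling to the network resolution averages 2×2 blocks, preserving
  summed intensity up to the factor 4.

## Synthetic digits corpus

The study corpus is a 10,000-image rotated handwritten-digits collection
(28×28, 8-bit, 1000 per class). To keep the package self-contained the
corpus is *emulated*: each digit 0–9 is a fixed set of polyline strokes
rasterised with a Gaussian pen, under a per-sample random affine jitter
(scale 0.9–1.1, shear ±0.08, translation ±4%) plus a rotation drawn
uniformly from ±45° (the published description states rotation without a
range). The corpus is a pure function of its seed. An IDX import hook
accepts real handwriting corpora.

What the emulation preserves: size, bit depth, class balance, rotation,
stroke-like spatial statistics, and determinism. What it does not: the
variability of real handwriting (writer styles, thickness variation,
broken strokes). Passing tests therefore demonstrate the *pipeline* —
simulation, training dynamics, arm comparison — on digit-like objects, not
performance parity on the original corpus; headline values obtained there
(NPCC ≈ −0.99, PSNR ≈ 80 dB after 40 epochs on 10,000 images) are outside
what the desk-scale conditions can or should reproduce.

Splits: test = 10% of all images, validation = 10% of the remaining pool,
train = the rest — at 10,000 images exactly 8100/900/1000. The split is
fixed once per dataset (not re-drawn per epoch) and unstratified by class,
with a stratified option.

## LGDiffNet

Architecture as described in the README; choices made where the
description is silent or ambiguous:

* **Pooling.** Both an initial 2×2 average pool (after the input block)
  and a 2×2 max pool at the end of every encoder stage are taken
  literally; this is also what balances the "one more upsample" before the
  output convolution, closing the spatial trace 256 → 128 → … → 4 → … →
  128 → 256.
* **Transition order** BN → ReLU → conv; dense-block convolutions are each
  preceded by BN + ReLU, receive the concatenation of the block input and
  all previous outputs, and add 16 feature maps each (growth), so a block
  maps C → C + 64 channels at full scale.
* **Decoder.** Transpose convolutions (2×2, stride 2 — non-overlapping)
  reduce channels to the mirrored stage width 2^(4+j); skip connections
  concatenate the matching encoder stage's pre-pool features (concatenation
  rather than addition — the channel counts differ). Decoder transitions
  mirror the encoder widths; the channel count entering each is derived
  from the concatenation arithmetic.
* **Padding** zero, "same", everywhere (required for the stated skips);
  **output activation** linear (the NPCC loss is invariant to affine output
  scaling); **initialisation** He-uniform; **BN** momentum 0.1, ε = 10⁻⁵.
  All config-exposed.
* Dense-block convolutions are plain 5×5 — no 1×1 bottlenecks.

**Engine.** The network runs on a compact reverse-mode autodiff tape over
numpy (float32, channels-last): im2col + BLAS convolutions with dilation,
non-overlapping transpose convolution, reshape-based pooling (max-pool
gradients split evenly across ties), batch normalisation with running
statistics, and an NPCC loss with an analytic gradient. Gradient
correctness is established by finite-difference checks and an independent
scipy correlation oracle in the test suite. Patch matrices under 64 MiB are
cached for the weight gradient; larger ones are rebuilt in the backward
pass to bound peak memory on full-scale graphs.

## Training protocol

Adam (β = 0.9/0.999, ε = 10⁻⁸), initial learning rate 10⁻⁴ halved every 10
epochs — lr(e) = 10⁻⁴ · 0.5^⌊(e−1)/10⌋ — 40 epochs at full scale, NPCC
loss, batch size 8 (not stated in the protocol; config-exposed). Inputs are
normalised by the dataset's peak intensity; targets are the original
(pre-optics) images scaled to [0, 1]. Batch order is reshuffled each epoch
from the training seed. The checkpoint with the best validation NPCC is
kept (the validation split exists, so it is used). A non-finite loss aborts
with the last finite weights retained. Per-epoch train/validation loss and
train MSE are logged to the run manifest (CSV via the CLI).

## Desk-scale preset and test problem sizes

The full 512-grid / 256-input / 5-stage configuration trains far too
slowly on one CPU to iterate on, so a scaled preset preserves the
geometry's dimensionless ratios instead of its absolute sizes: 128×128 grid
at 10 µm pitch, w₀ = 180 µm, z = 2 mm per leg, diffuser correlation length
25 µm (2.5 pixels, vs 2.3 at full scale), phase std 2π, network input
64×64 with 2 stages, kernel 3, transition widths 16/32, growth 8 (176 k
parameters). Beam-to-grid ratio, beam-to-object ratio and z/z_R all track
the full-scale values, and the largest matched Gaussian still captures
≥ 99% of its power.

The scaled study conditions used by the acceptance suite and
`scripts/acceptance.py`: 500 synthetic digits (50 per class), one shared
diffuser realisation, both illumination arms simulated on identical
corpora, three training seeds per arm (one in the script), three epochs.
The 8-sample overfit check — a wiring/capacity test, not a protocol run —
uses lr 10⁻³ since the published schedule's early-training rate is
irrelevant to it. Under these conditions reconstructions reach NPCC ≈ −0.5
to −0.75 and the comparison is read *directionally*: the seed-averaged
reconstruction correlation of the vortex arm is required to be at least
that of the Gaussian arm, replicating the claim's direction, not its
magnitudes.

## Metric conventions

* **NPCC** is the negated Pearson ratio of the two pixel populations, so
  −1 is a perfect reconstruction and minimising the loss maximises
  correlation. (Published tables occasionally print the experimental
  values with a positive sign; the text values near −0.98 fix the intended
  convention, and the sign discrepancy is treated as typesetting. Likewise
  −0.9956 appears in prose where −0.9959 appears in the table for the same
  condition; neither is adjudicated here and no check depends on it.)
* **MSE/PSNR** on the 0–255 dynamic range: PSNR = 10 log₁₀(255²/MSE).
  This convention is *validated* rather than assumed: plugging the
  reported MSE values 0.0006 and 0.0008 into it reproduces the reported
  80.34 dB and 79.09 dB within 0.05 dB (rounding of the 4-decimal MSE).
  Zero MSE reports PSNR as infinite with a flag rather than raising.
* **Dice** binarises at 127.5 on the 0–255 scale after affine-normalising
  the reconstruction to the truth's range (no binarisation rule is stated;
  affine normalisation is the natural partner of a scale-free loss). Two
  empty masks score 1. The same affine normalisation precedes MSE, since a
  network trained on a scale-invariant loss outputs arbitrary units.
* **Aggregation** over a test set: per-image NPCC/MSE/Dice are averaged;
  PSNR is computed from the averaged MSE (one MSE/PSNR pair per condition).

## Known limitations

* Scalar model: no polarisation, partial coherence, or nonlinearity; the
  diffuser is a thin screen, not a volume scatterer.
* Ideal detector: no shot noise, readout noise or 8-bit quantisation (an
  optional quantisation flag exists on export, not in the default chain).
* The desk-scale directional comparison is a stochastic check over a small
  seed ensemble; single seeds can land either side of a tie.
* The synthetic corpus is digit-like, not handwriting; absolute
  reconstruction metrics do not transfer to the original corpus.
* The autodiff engine is single-threaded numpy; full-scale 40-epoch
  training is out of reach here (the architecture is still built, shape-
  checked and gradient-checked at full scale).
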