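# vortexdiff

Imaging through diffuse media — fog, tissue, ground glass — destroys images:
multiple scattering scrambles the light field into speckle long before it
reaches a camera. `vortexdiff` is a simulation and reconstruction toolkit for
one strategy against this: illuminate the object with **several orthogonal
modes of structured light** — Laguerre-Gaussian (LG) vortex beams carrying
orbital angular momentum — record one speckle image per mode, and let a
convolutional encoder–decoder (**LGDiffNet**) invert the scrambling. The
package simulates the whole optical bench, trains the network, and measures
whether multi-mode vortex illumination beats spot-size-matched Gaussian
illumination, mirroring a published proof-of-concept in computational
imaging for biomedical applications.

Everything runs from Python on a single CPU; no data downloads and no GPU
framework are required (the network runs on a compact numpy reverse-mode
autodiff engine built into the package).

## What is simulated

**Illumination.** LG modes LG_p^l sampled at their waist,

    u(r, φ) ∝ (√2 r / w)^|l| · L_p^{|l|}(2r²/w²) · exp(−r²/w²) · exp(−i l φ),

with topological charges l = 0, 2, 4 (radial order p = 0) for the vortex
arm, and for the comparison arm three Gaussian beams with the matched spot
sizes w₀√(1+l). Defaults: λ = 632.8 nm, w₀ = 0.63 mm, 5 mW per mode.

**Scene.** A two-leg split-step chain: the beam picks up the object's phase
(a digit image mapped linearly onto 0…2π), propagates z = 2 cm by the
angular-spectrum method, passes a Gaussian-correlated random phase screen
standing in for a grit-220 ground-glass diffuser (correlation length 15 µm,
phase std 2π — fully developed scattering), propagates a second leg, and the
detector records intensity on a 512×512 grid at 6.45 µm pitch. One
acquisition per mode fills one channel of a 512×512×3 stack, 2×2-block
averaged to 256×256×3 for the network.

**Reconstruction.** LGDiffNet: a three-branch dilated (1, 2, 3) 5×5 input
block, five encoder stages of transition layer (BN → ReLU → conv with
2^(4+i) kernels) + dense block (4 × 16 kernels, 5×5) + max pooling, a
bottleneck, five mirrored decoder stages with 2×2 transpose-convolution
upsampling and skip concatenations, and a final upsample + convolution to
one channel — 48 M parameters at full scale. Training follows the published
protocol: Adam, lr 10⁻⁴ halved every 10 epochs, 40 epochs, negative Pearson
correlation (NPCC) loss, 90/10 train/test split with 10% of the training
pool for validation.

**Metrics.** NPCC (−1 = perfect reconstruction up to a positive affine
map), MSE on the 0–255 scale, PSNR = 10 log₁₀(255²/MSE), Sørensen-Dice
overlap of the binarised images.

A desk-scale preset (`DESK_SCENE`/`DESK_NET`: 128×128 grid, 64×64 two-stage
network, 176 k parameters) scales the same geometry down so the full
simulate → train → evaluate cycle runs in minutes on one CPU.

## Worked example

```bash
python examples/01_beams_and_propagation.py
```

```
Matched Gaussian waists (w0 sqrt(1+l)):
  l = 0: 0.630 mm
  l = 2: 1.091 mm
  l = 4: 1.409 mm

Mode powers and azimuthal winding numbers:
  l = 0: power 5.000 mW, winding 0.000
  l = 2: power 5.000 mW, winding 2.000
  l = 4: power 5.000 mW, winding 4.000

Pairwise mode overlaps (should be ~0; OAM modes are orthogonal):
  <l=0|l=2> = 1.60e-15
  ...
Focused beam (w0 = 50 um, Rayleigh range 12.4 mm) vs analytic w(z):
  z = 2.0 cm: measured 94.8 um, analytic 94.8 um, power error 1.7e-16
```

Each generated mode carries exactly its nominal power, winds its phase by
l·2π around the axis, is orthogonal to the other charges, and free-space
propagation reproduces the closed-form Gaussian beam expansion while
conserving power to machine precision.

The end-to-end miniature (`python examples/05_desk_pipeline.py`, ~4 min)
simulates 200 digits through the diffuser in both arms, trains the desk
network three epochs on each, and prints the four-metric comparison table:

```
Parameters                  Gaussian beams    Vortex beams
MSE                         5203              4969
PSNR (dB)                   10.97             11.17
NPCC                        -0.4763           -0.4739
Sørensen-Dice coefficient   0.1596            0.1798
```

At this tiny scale the reconstructions are rough (NPCC ≈ −0.5 rather than
the −0.99 reached by 10,000-image, 40-epoch training) — the point is the
side-by-side protocol; the seed-averaged comparison lives in the acceptance
suite. The other examples cover the diffuser scene (`02`), the synthetic
rotated-digits corpus (`03`) and the network layer table (`04`).

A thin CLI wraps the same pipeline:

```bash
vortexdiff simulate --preset desk --arm vortex --n-per-class 20 --out vortex.h5
vortexdiff train --data vortex.h5 --net desk --epochs 3 --out run_vortex
vortexdiff evaluate --checkpoint run_vortex/model.npz --data vortex.h5 --report report.json
vortexdiff compare --a run_vortex/manifest.json --b run_gauss/manifest.json
```

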