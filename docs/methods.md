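# Methods

This note documents the models, the synthetic data the package generates,
the numerical choices, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Imaging model

**Camera.** Pixels are 160 nm (back-projected); gain and quantum efficiency
are folded into unity so pixel values are photons. Noise is per-pixel
Poisson on signal + background plus Gaussian read noise. Defaults:
background 10 photons/px/frame, read noise 1.5 e⁻ RMS. These are stand-ins
chosen as typical of buffer autofluorescence and sCMOS readout in STORM
acquisitions; the real acquisition parameters behind the experimental
library are not published, so both are configurable and flagged in the run
config.

**PSF.** An isotropic 2D Gaussian with σ = 102 nm, chosen so the FWHM
(2.355 σ ≈ 240 nm) matches the diffraction limit for AF647 emission
(~670 nm) at NA 1.4: the Abbe limit λ/2NA ≈ 239 nm. Anisotropic widths
(σ<sub>x</sub>, σ<sub>y</sub>) are supported. Rendering integrates the
Gaussian **analytically over each pixel area** (error-function differences
per axis), not center-point sampling; total flux in a large crop then
equals the photon count to numerical precision, which is what makes the
fine-grid quadrature oracle in the tests meaningful.

**Coordinates.** Global origin at the top-left corner of pixel (0,0);
x rightward, y downward; pixel (row i, col j) covers
[j·160, (j+1)·160) × [i·160, (i+1)·160) nm. Emitter coordinates are
continuous nm. Every crop records the global offset of its top-left
corner, so coordinates survive cropping and zero-padding round trips.

**Photons.** Per-blink photon counts follow a truncated lognormal
(median 5000, geometric SD 1.8, truncated to [500, 50000]). This emulates
the broad right-skewed photon distribution of single AF647 switching
events; the published distribution is shown only graphically, so the
parameters are a design choice made once and flagged in config.

**Blinking.** A two-state Markov chain per molecule: P(off→on) = 10⁻³ per
frame, P(on→off) = 0.5 (mean on-time 2 frames), started from the
stationary distribution (on-fraction p_on/(p_on+p_off) ≈ 0.002). These
rates are not published; they give realistic sparse activation at the
default 2000-frame desk scale (8000 frames under `--profile paper-scale`).

## Single-emitter library

Each library record is a noisy 7×7 crop whose emitter lies uniformly
within the central pixel (as detection-centered experimental crops do),
together with its true position/photons and a least-squares fit of the
pixel-integrated Gaussian (amplitude, center, σ<sub>x</sub>, σ<sub>y</sub>,
constant offset; trust-region with bounds keeping the center inside the
crop, initialization at the photon centroid with σ = 1 px). A degenerate
(flat) crop or non-convergence raises a fit error rather than returning
garbage. Spot statistics follow the field's conventions: photon count =
plain pixel sum, relative area = 2σ<sub>x</sub>·2σ<sub>y</sub>,
ellipticity = σ<sub>x</sub>/σ<sub>y</sub>.

Detection in frames uses a difference-of-Gaussians band-pass
(σ = 1 px and 3 px) with a robust threshold (5 × 1.4826·MAD above the
median) and greedy non-maximum suppression. The band-pass is used for
detection only; the raw pixels are what gets cropped, fitted, and fed to
the networks (a config choice — whether the reference pipeline filtered
the network inputs is ambiguous, and preserving photon statistics is the
conservative default).

## Multi-emitter dataset construction

Two-to-four emitter spots are derived, not simulated from scratch: target
coordinates are drawn uniformly inside a 240 nm disk on a 1 nm grid (all
pairwise distances then stay below the diffraction limit), each selected
library record is translated so its *fitted* emitter position lands on its
target, and the translated images are summed. The targets become the
labels, so ground truth is available by construction. Fixed-separation
evaluation subsets use a constrained-pair sampler (separation uniform in
an interval such as 30 ± 2 nm, orientation uniform).

**Sub-pixel translation.** Fourier shift of the 7×7 crop zero-padded
3× (bilinear available via config). The full padded array is kept when
pasting, which preserves total flux exactly (a phase ramp does not touch
the DC component). A genuine limitation: at σ/pixel = 0.64 the spot is
sampled *below* Nyquist, so no sample-based interpolator can reproduce the
truly shifted spot exactly — measured peak errors are ~3–6% for Fourier
and spline interpolation and ~15–19% for bilinear. Fourier shift is kept
as the default (best accuracy, exact flux). Any pipeline that derives
multi-emitter spots by translating sampled single-emitter crops shares
this floor; the corresponding oracle test asserts the achievable 8%-of-peak
bound plus flux conservation.

**Canvas and jitter.** Merged spots sit on a 15×15 canvas whose center
pixel carries the centroid of the targets plus a uniform ±0.5 px jitter,
so the centroid is not a trivial cue (at inference the crop center comes
from a noisy single-Gaussian fit).

**Label ordering.** The per-coordinate MSE loss is order-sensitive, so
emitters are canonically sorted by x (ties by y). A permutation-invariant
variant (minimum of the loss over emitter orderings) is available via
`loss_variant="permutation-min-mse"`; the canonical ordering is the
default because it matches the plain-MSE recipe. Evaluation is always
ordering-free (Hungarian matching).

**Splits.** Train and test use disjoint source-molecule pools, so an
experimental (or synthetic) spot reused across merged images can never
leak between splits.

**Summed noise.** Merged spots sum noisy crops, so a two-emitter spot
carries ~2× background in the overlap of the two footprints. This is a
property of the derivation itself (summing real crops would do the same)
and is left in by default; background subtraction before merging is
available via config.

## Networks

With no deep-learning framework among the dependencies, the networks are
compact fully-connected residual models implemented in numpy: an input
projection (225 → 256), two residual blocks
(relu(x + W₂ relu(W₁x + b₁) + b₂), skip connections fusing low- and
high-dimensional features — the same motivation as residual CNN
backbones), and a linear head. The classifier head ends in a softmax over
counts; the localizer for count *I* emits 2*I* coordinates in nm relative
to the crop center (bounded targets condition the regression; a documented
transform returns them to the global frame).

Inputs are divided by a fixed global constant (1000 photons), **not** the
per-image maximum: the absolute photon scale is a physical cue
(two-emitter spots carry roughly twice the flux) that per-image
normalization would destroy.

Training: Adam, batch 64, cosine-annealed learning rate, decoupled L2
weight decay, deterministic given the seed. Two profiles:

| parameter | desk (default) | paper-scale |
|---|---|---|
| epochs | 60 (40 classifier) | 400 |
| learning rate | 10⁻³ → 10⁻⁵ | 10⁻⁵ → 10⁻⁸ |
| weight decay | 10⁻⁴ | 0.01 |
| training spots | ~20–24k | 280k |

The paper-scale schedule is preserved verbatim as a profile; the desk
profile uses a larger initial rate because the compact network trained
from scratch for tens of epochs would barely move at 10⁻⁵. Cross-entropy
is implemented as the standard non-negative form −Σ p log q (the printed
Σ p log q convention would be ≤ 0).

## Inference

Per frame: detect spots (band-pass + maxima, detections within 2 px
merged), refine each center with a single-Gaussian fit on a 7×7 crop (for
a multi-emitter spot this is only an approximate center — all the crop
placement needs), cut 11×11 around the fitted center, zero-pad to 15×15,
classify, and route to the count-matched localizer. Class-probability ties
resolve to the lower count (conservative). Spots touching the frame border
are zero-filled and flagged in the output table. Output is a
ThunderSTORM-dialect CSV (`frame, x [nm], y [nm], ...`) with extra
`count`/`confidence` columns.

## Evaluation

RMS is computed per spot after minimum-cost matching on squared distances
(any other pairing inflates the error artifactually; matching equals
brute-force permutation search, tested up to 4 emitters). When the
predicted count differs from the truth the spot is excluded from RMS and
tallied separately — the regression error is undefined across lists of
different lengths. Distance bins default to {0, 60, 120, 180, 240} nm.
The midpoint baseline d/(2√2) — predicting both emitters of a pair at
their midpoint — is the closed-form lower bar used in tests.

SSIM uses 7×7 uniform windows, sample covariance, C₁ = (0.01 L)²,
C₂ = (0.03 L)², mean over fully interior windows (verified against an
independent implementation to 10⁻⁶). Spike canvases are 8× upsampled and
convolved with a σ = 1 high-resolution-pixel Gaussian; the reference
kernel is not published numerically, so this is configurable.

## STORM simulation

Ultrastructures are disks (default 240 nm) with a center-weighted radial
Gaussian density (σ = diameter/4, rejection-sampled inside the disk) and
50–550 molecules. Each molecule blinks independently; active molecules are
rendered at their layout positions and the frame receives camera noise.
Ground truth records every emission event and its spot group (single-
linkage clustering of co-active molecules at 240 nm), so every rendered
spot decomposes exactly into its contributors. The classical baseline fits
one Gaussian per detected spot and treats it as one molecule, so its
localization count is at most the event count, with equality only without
co-activations.

## Benchmark problem sizes

The desk-scale benchmark experiments (`multispot.benchmarks`) use: a
3000-molecule library; 20k balanced one/two-emitter spots (90/10
molecule-disjoint split) and 40 epochs for classification; 24k two-emitter
training pairs and 60 epochs for localization; evaluation sets of 3000
disk-uniform pairs, 1200 pairs conditioned on separation < 60 nm (the
conditional distribution of the full generator, not a uniform-in-interval
shortcut, which would be easier), and 1200 pairs at 30 ± 2 nm; 10k spots
for cross-batch generalization with the photon median shifted +10% and a
fresh seed. These sizes are the package's chosen desk-scale twins of the
full-scale experiments (280k training spots, ResNet-50-class backbone);
they run in minutes on one CPU.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of an experimental
single-fluorophore library — pixel-integrated PSF, shot noise and
background, broad photon distribution, blinking, detection-centered crops
— but not its full phenomenology: no drift, no dipole/aberration PSF
asymmetries, no EMCCD excess noise, no fluorophore photophysics beyond
two-state blinking, and the PSF family used to *generate* spots is the
same family used to *fit* them. Counting and localization quality measured
here is therefore an upper bound on what identically configured networks
would achieve on real spots: passing tests demonstrate that the pipeline
machinery (dataset derivation, losses, routing, matching, metrics) is
correct and that the networks extract the available information, not that
a given accuracy will transfer to any particular microscope.

Other known limitations: emitter counts are capped at 4 per spot and one
diffraction-limited region; structures larger than the diffraction limit
are out of scope; 2D only; the one- vs two-emitter *relative-area* means
of the synthetic populations differ by ~12% (linear spot size ~6%) at
σ = 102 nm — heavily overlapping, but slightly more separated than ideal
"indistinguishable" morphology, because the generator's σ sits exactly at
the diffraction-limit width.
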