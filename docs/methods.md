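# Methods

This note documents the models, estimators and numerical choices behind
`srqt2`, in the order data flows through the pipeline, together with the
design decisions that were genuinely open and the limitations we know
about.

## Signal model and scope

Every stage assumes single-compartment transverse relaxation,
`S(TE) = M0 · exp(−TE / T2)`, with magnitude (Rician) detection noise.
Echo-train amplitude modulation, T1 saturation, stimulated echoes, B0/B1
inhomogeneity and multi-compartment relaxation are deliberately outside
the model: echo train length and repetition time travel with each
protocol as metadata so configurations mirror a real protocol sheet, but
they do not enter the simulated signal. White matter in particular is
known to be multi-compartment; a single-T2 fit of it remains a useful,
reproducible summary statistic, which is the use case here.

## Phantoms

Two generators provide ground truth (`M0` map, `T2` map, integer ROI
labels on one grid):

* **Multi-element phantom** — spherical elements (default: ten, T2
  log-spaced 40–300 ms, 9 mm radius, in the size range of commercial
  relaxometry phantoms) on a ring inside a cylindrical body of long-T2
  filler liquid (1500 ms). The seed rotates the ring.
* **Brain phantom** — an ellipsoidal head with six white-matter ROIs at
  adult-white-matter T2 values (98–118 ms), surrounding tissue at
  130 ms, and two long-T2 (1500 ms) ventricle blobs that stress the
  mono-exponential fit. The seed jitters ROI centers (±1.5 mm) and head
  axes (±2%), so different seeds play the role of different subjects
  while true T2 values stay fixed. The corpus-callosum compartment is
  deliberately thicker (10 × 18 × 9 mm semi-axes) than the anatomical
  structure so that interior voxels survive 5 mm slabs on every
  acquisition grid; these phantoms are fitting testbeds, not atlases.

`M0` is 1000 arbitrary units everywhere inside the body, which makes the
signal-to-noise conventions below unambiguous. Structure boundaries get
a one-voxel partial-volume ramp in `M0`/`T2`; the label maps mark only
pure-core voxels, and ramp voxels belong to no label.

What the phantoms do **not** emulate: realistic anatomy and texture,
within-ROI heterogeneity, T1/diffusion properties, field maps. Passing
recovery tests on them demonstrates correctness of the measurement
chain, not performance on real brains.

## Acquisition simulator

One simulated acquisition applies, in order: (1) voxelwise TE weighting
on the phantom grid; (2) a single rigid motion per acquisition
(inter-scan motion model), applied as a world-space resample; (3) ideal
boxcar integration over the slice thickness along the orientation's
slice-normal axis (axial→Z, sagittal→X, coronal→Y), implemented with
exact cell-overlap weights so non-integer spacing ratios remain exact
for piecewise-constant inputs; (4) in-plane block averaging to the
acquired in-plane spacing; (5) Rician noise,
`sqrt((S+n1)² + n2²)` with `n1, n2 ~ N(0, σ²)`, seeded.

The slice profile is an ideal boxcar because the estimator chain can
then be verified against an exact brute-force oracle; a measured profile
would only blur the comparison. Noise is parameterized by the
per-channel Gaussian σ on the *acquired* (downsampled) grid. Two
presets define the simulated regimes: σ = 25 ("phantom mode",
M0/σ = 40) and σ = 66.7 ("in-vivo mode", M0/σ = 15).

Protocol factories reproduce the three acquisition designs: the five-TE
single-orientation reference (TE 60/100/150/200/300 ms, TR 2200 ms,
13:37 total), the three-TE single-orientation set, and the three-TE
multi-orientation set (TE 122.8/182.4/241.6 ms, TR 2000 ms, 11:41
total); all at 1.5 × 1.5 mm in-plane, 5 mm slices. The classical SNR
proportionality (voxel volume × √time) relates the designs:
(11.25/3.375)·√(817/701) ≈ 3.6 between the reference's acquired voxels
and the reconstructed isotropic voxels.

## Rigid registration

Six-parameter rigid registration (Euler angles + translation about the
fixed-grid center) maximizes normalized cross-correlation by default
(mutual information and MSE are selectable) with a bounded Powell search
over a three-level coarse-to-fine pyramid. Several choices here came
out of failures we could measure, and are worth recording:

* **Blur matching.** Each image is smoothed so the *total* per-axis blur
  (acquisition PSF, modeled as a boxcar of the voxel size with SD
  `spacing/√12`, plus the added Gaussian) reaches a common target
  (3.5·√level mm). Without this, orthogonal thick-slice pairs reward
  tilted poses whose interpolation blurs the sharp axis of one image to
  match the other.
* **Half-voxel sampling.** The metric samples the fixed image midway
  between voxel centers, so fixed values are interpolated exactly like
  moving values are at a generic pose. On-lattice sampling makes the
  identity the only pose whose samples keep raw, un-averaged noise, and
  the metric then *prefers misalignment* at low SNR.
* **Capture range.** The search is bounded to ±15° / ±20 mm around the
  initialization — the physical scale of inter-scan subject motion.
  This also keeps the optimizer out of distant spurious optima, e.g.
  the ring symmetry of a multi-element phantom, where rotating by one
  element spacing re-aligns the pattern.
* **Metric choice.** Mutual information handles echo pairs whose
  contrasts are not related by any single intensity mapping, but it is
  nearly flat when one tissue class dominates the joint histogram and it
  will happily permute the elements of a symmetric phantom; correlation
  fails in the opposite direction (mild blur-tilt reward on extreme
  cross-contrast pairs, about an order of magnitude shallower). The
  default is correlation; the residual cross-contrast tilt is at the
  degree level and is absorbed by the interior-ROI statistics below.
* Ties in flat metric regions resolve to the smallest transform via a
  tiny magnitude penalty, and sub-resolution parameters (<1e-4) snap to
  zero, so self-registration returns exactly the identity.

## Super-resolution template construction

The three anisotropic inputs are fused by iterative template
construction on an isotropic grid spanning the union of their fields of
view:

1. every input is trilinearly upsampled and averaged (per-voxel mean
   over valid contributions, after scaling each input to unit median
   foreground intensity so no echo dominates the anatomical template);
2. first registration pass: each input aligns to the **leave-one-out**
   average of the others — the full template contains the input's own
   copy, which would anchor a badly-moved acquisition onto its own
   ghost, while the leave-one-out target recovers large motions in one
   step and is symmetric in input order;
3. subsequent passes (three total by default) register to the full
   template, whose self-copy now sits at the nearly-correct pose and
   stabilizes the ensemble against collective drift;
4. finally, the componentwise **median transform** is factored out of
   all per-input transforms. The template frame is unobservable in
   principle; median re-centering pins it to the consensus pose, which
   is robust to a single badly-moved input and independent of input
   order.

The "maximum-likelihood" intensity fusion is the validity-mask-weighted
mean with equal weights — the ML estimator under equal Gaussian noise.
The per-input aligned volumes returned for fitting are *not* intensity
scaled: the fit needs the true TE-dependent magnitudes. Forward and
inverse world transforms per input are part of the result and serialize
as plain-text 4×4 matrices.

Measured behavior on the standard phantoms (all asserted in the test
suite): a 4 mm shift of one input is recovered to 0.3 mm; relative
translations of three mutually-moved inputs to ~0.1 mm; relative
*rotations* carry a consensus floor of roughly half a degree, which the
ROI-level accuracy bounds absorb. The template's RMSE against ground
truth beats every single-orientation upsampling.

## Adaptive non-local-means denoising

Each aligned echo image is filtered independently with its own noise
map (noise levels differ across echoes because signal decays while the
noise floor does not). The noise map comes from six-neighbor
pseudo-residuals scaled by √(6/7), robustly summarized by a 5³ median
filter (×1.4826 to convert the absolute-value median to an SD). Weights
are `exp(−‖patch_i − patch_j‖² / (h·σ(x)²·N_patch))` with 3³ patches, a
7³ search window and h = 1; the self-weight equals the maximum neighbor
weight. The output is a convex combination of inputs, hence bounded and
non-negative.

Rician bias is **not** corrected: the filter reduces variance around the
biased magnitude mean. This is the single most consequential limitation
at low SNR (next section).

## T2 fitting

Voxels enter the fit when the shortest-TE intensity exceeds three
background-noise SDs (estimated from the image itself) and all validity
masks agree. The log-linear stage is unweighted (the nonlinear stage
refits the untransformed residuals anyway); non-decaying voxels are
clamped to the upper T2 bound and flagged. The simplex stage runs a
vectorized Nelder–Mead over (M0, T2) for *all* masked voxels
simultaneously — standard reflection/expansion/contraction/shrink with
coefficients (1, 2, ½, ½), 100 iterations, relative RSS tolerance 1e-6,
with converged voxels dropping out of the working set. The best vertex
never worsens, so the final RSS is bounded by the initialization's. T2
is clamped to [1, 3000] ms; if clamping would worsen the fit, the
initialization is returned instead.

## Evaluation

Agreement uses ICC(A,1) — two-way, absolute agreement, single measures —
because the scientific claim is that two protocols produce the *same
numbers*, not merely proportional ones. The implementation is checked
against an exact-arithmetic ANOVA oracle and an independent statistics
package. T2-to-noise ratio is ROI mean over ROI sample SD (n−1), with a
capped sentinel for constant ROIs.

ROI statistics use **interior-only** labels: a voxel counts toward an
ROI only if the window of one slab thickness plus two in-plane voxels
(8 mm) centered on it lies entirely inside the ROI's pure core. This
emulates drawing ROIs on structure interiors; without it, thick-slab
partial volume with long-T2 neighbors (ventricles, phantom filler)
dominates the ROI means.

## Noise regimes, agreement studies, and the Rician floor

The agreement studies pair ROI-mean T2 from the multi-orientation SR
pipeline against the five-TE reference on identical phantom instances
and noise realizations: ten element means for the multi-element study
(phantom mode), and six ROI means × five brain instances (30 pairs,
in-vivo mode). The denoising switch applies to the aligned multi-TE
stack of *both* branches, so with/without comparisons isolate the
filter's effect rather than a between-branch processing asymmetry.

A structural limitation dominates the low-SNR regime. The magnitude
noise floor is `σ·√(π/2)`; once a late-echo signal approaches it, the
measured decay flattens and the fitted T2 rises — denoising cannot
remove this because the floor is a property of the mean, not the
variance. Concretely, with the 122.8–241.6 ms echo train: at in-vivo
mode (σ = 66.7) white-matter signals at the last echo sit at 1–2 σ, so
voxelwise T2 is biased upward by ~10–15% and the between-ROI contrast of
a 98–118 ms ladder is compressed toward the noise-floor fit; at phantom
mode (σ = 25) elements below ≈60 ms are unmeasurable *at any plausible
SNR* because their first-echo signal is already within a few σ of zero.
The acceptance studies run at the configured modes regardless and report
what the estimator chain actually produces; the oracle suites (noiseless
exactness, brute-force equivalences, known-motion recovery) are the
correctness guarantees, and the agreement statistics at these noise
levels characterize the regime honestly rather than flatter it. A
Rician-aware fit (noise-floor term in the model, or squared-magnitude
correction in the filter) is the obvious extension and is deliberately
out of scope here.

## Problem sizes, determinism, degenerate inputs

Default experiments use a 96³ ground-truth grid at 1.5 mm (head and
phantom geometry in millimeters, so coarser test grids stay valid), one
phantom instance for the multi-element study and five for the brain
study. All randomness flows from explicit seeds: phantom instance seeds
are `base + instance`, per-acquisition noise streams are derived
arithmetically from (base, instance, branch, index), and identical
configurations are byte-stable. Degenerate inputs have defined behavior:
all-zero volumes fit to an empty mask; equal signals flag infinite T2
rather than raising; empty ROIs are flagged rows, not dropped; constant
ROIs report a capped T2-to-noise sentinel; out-of-field voxels are
zero-filled and excluded via validity masks.
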