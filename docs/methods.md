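# Methods

`odepkit` implements an end-to-end electrokinetic-fingerprinting analysis
for single cells stimulated by optically-induced dielectrophoresis (ODEP),
together with a synthetic video/cohort generator that makes every stage
testable without patient data. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic tests do and do not demonstrate.

## Measurement model

A cell in suspension sits between two light-defined "virtual electrodes"
60 μm apart. A 10 Vpp signal is applied to one electrode at a time,
stepping through 26 frequencies from 150 kHz down to 25 kHz in 5 kHz steps
while the active electrode alternates A, B, A, … One video clip is
recorded per frequency at 20 fps and 0.45 μm/px; clips are concatenated
and the first 1,000 frames (50 s) form the analysis window. Above the
dielectrophoretic crossover frequency the cell is attracted toward the
active electrode (pDEP) and oscillates at roughly 0.2 Hz as the electrodes
alternate; near crossover it is quasi-static; below it the force reverses
(nDEP).

Two descriptor families summarize a cell:

- **Centroid (absolute frame):** the x/y centroid displacements relative
  to the first frame are decomposed by a two-order wavelet scattering
  transform and time-averaged, giving 568 descriptors.
- **Local (centroid frame):** PIV between consecutive centroid-centered
  ROIs gives per-frame deformation fields, reduced to three series — the
  spatial means x̄(t), ȳ(t) of the two components and the spatial mean
  θ̄(t) of the cosine of the per-node phase angle — each referenced to its
  first sample. Seven statistics per series (SD, mean absolute deviation,
  skewness, non-excess kurtosis, max, min, approximate entropy) give 21
  descriptors.

Classification is three-class (fertile control CTRL vs. the pathological
RIF and uRPL endometrial conditions) at the single-cell level with
leave-one-patient-out (LOPO) cross-validation, and at the patient level by
majority voting over random cell groups.

## Stage-by-stage choices

### Tracking and ROI extraction

The tracker is a deliberately simple substitute for a dedicated tracking
suite: per frame, Otsu binarization, connected components, nearest-
component linking to the previous position, then refinement by the
intensity-weighted (above-threshold excess) centroid of the chosen
component. The weighted refinement roughly halves frame-to-frame jitter
relative to the binary-mask centroid (≈0.04 px vs ≈0.09 px on a static
synthetic cell), which matters because ROI re-centering at the *rounded*
centroid turns tracker jitter into coherent ±1 px content shifts whenever
the estimate crosses a pixel boundary. Coordinates are 0-based (x =
column, y = row); rounding is half-away-from-zero; out-of-frame ROI pixels
are filled by edge replication (zero-fill would create artificial
gradients for PIV) and flagged.

### Motion-area segmentation

The cumulative image is the pixelwise sum of per-frame 1st/99th-percentile
stretches, clipped to [0, 1] before summation (the stretch can exceed the
range; clipping keeps every frame's contribution bounded), then min–max
scaled. Binarization uses Otsu's threshold on a 256-bin histogram with
strict `>`. The cell motion area is the hole-filled largest non-border
component containing the centroid; the cytoplasm is the corresponding
component of the complement intersected with a circle of the
Hough-estimated radius; the boundary band is their exact set difference
(an identity asserted on every returned mask object). Hole filling is
applied after component selection. If the boundary band is empty or equals
the whole motion area, the threshold is swept down (p = 1 − 0.1 n,
n = 1…10) and then up (p = 1 + 0.1 n while p·th_O < 1; the upward
increment is set equal to the downward one); on total failure the Otsu
cell mask is returned with `converged=False`. The default Hough search
range is 30–80 px (cell radius ≈ 50 px at full scale) and is configurable;
the pipeline scales it with the configured cell radius.

### PIV

Two-pass windowed FFT cross-correlation: a coarse pass at twice the final
window predicts the field, the second frame is shifted by the bilinearly
interpolated prediction, and the final pass runs at the 10 px window
(≈1/10 of the cell diameter) with 50% overlap — 29×29 nodes on a 151 px
ROI. Windows are zero-mean normalized; correlation is circular; each peak
is refined by a 1-D three-point Gaussian fit per dimension, falling back
to the integer peak when a neighbour correlation is non-positive. Peaks on
the correlation border and zero-variance windows are invalid; vectors are
masked *after* sub-pixel refinement (masking is geometric). Frames are
preprocessed by linear min–max mapping plus CLAHE (8×8 tiles, clip limit
0.01 — unstated in the protocol, standard values, configurable). On
noise-free synthetic videos the estimator recovers the generator's exact
fields with median absolute error ≈ 0.05–0.1 px per component.

### Deformation kinetics

The phase of a displacement vector is the four-quadrant angle atan2(v, u);
the orientation series is the spatial mean of cos θ over valid nodes, so
θ̄ ∈ [−1, 1]: values near ±1 mean deformations aligned with the electrode
axis, values near 0 mean orthogonal or mutually cancelling orientations.
Zero-magnitude nodes have no orientation and contribute cos θ = 0. Frames
with no valid node are dropped from the series (counted and logged).

Approximate entropy follows the standard regularity statistic: length-m
blocks (m = 2) compared under the Chebyshev distance at radius
r = 0.2·SD (r_factor configurable in [0.1, 0.4]), self-matches excluded,
φ_m = mean over blocks of ln(count/(B−1)), ApEn = φ_m − φ_{m+1}. A block
with no neighbour keeps its self-match so the logarithm stays finite; a
constant series returns 0. Kurtosis is non-excess (Gaussian → 3) and all
moments are population-normalized. A vectorized O(N²) implementation is
used; the test suite pins it to an independent direct-count oracle at
1e−12.

### Wavelet scattering

No scattering-transform package is assumed; the transform is implemented
directly: analytic constant-Q Gaussian band-pass filters on the FFT grid,
modulus envelopes, a second filtering stage, and full-window time
averaging (the `muS` prefix). Full-window averaging makes the descriptors
exactly invariant to circular time shifts.

The filter-bank configuration is constrained by the two published center-
frequency spans ([0.06–9.1] Hz first order, [0.07–8.3] Hz second order at
20 Hz) and by the descriptor total of 568, with the total treated as
authoritative. A search over geometric banks gives: 57 first-order center
frequencies (≈8 per octave), 8 second-order (≈1 per octave), second-order
paths restricted to f₂ < f₁ (226 pairs), plus one order-0 (window-average)
path per axis: (1 + 57 + 226) × 2 axes = 568. This coincides with the
common Q = [8, 1] two-order design for slow biological signals, which
supports the reading. Descriptor names encode axis, order and center
frequency (e.g. `muS1x_0.192Hz`, `muS2x_[1.38,0.07]Hz`) in a fixed
canonical order: per axis, order 0, then order 1 by descending frequency,
then order 2 lexicographically by (f₁, f₂) descending, x before y. Banks
dilate covariantly with the frame rate; a window shorter than one period
of the slowest filter is rejected.

### Feature selection and classification

The multiclass AUC of a feature is the maximum over all class pairs and
one-vs-rest splits of max(AUC, 1−AUC), computed rank-based with ties at
0.5; it is ≥ 0.5 by construction. Filtering keeps features strictly above
0.6 (centroid family) or 0.75 (local family); the family→threshold
assignment follows the order the two families are introduced in and is
configurable. Selection is plain forward SFS (no floating removal) scored
by the nested-LOPO balanced-accuracy error of an LDA on the training
patients, stopping when the error reduction relative to the mean of the
previous 5 step errors falls below 1e−6; ties are broken by feature-name
order, so selection is deterministic. The inner scorer is a closed-form
uniform-prior LDA on z-scored features with a small (1e−8) diagonal guard
on the pooled covariance; the reported per-round models use scikit-learn's
LDA (SVD solver, uniform priors, z-scored inputs), switching to an
eigen-solver with shrinkage when classes are small relative to the feature
count or the covariance is singular (logged). Canonical scores and
loadings are exposed for explainability; the final all-data refit uses the
features selected in at least half the LOPO rounds.

Per LOPO round, filtering, selection, scaling and fitting see training
patients only; a SHA-256 checksum of each round's training matrix is
recorded so the absence of leakage is auditable. Majority voting samples g
cells per patient without replacement (1,000 Monte-Carlo repetitions by
default), assigns the patient by plurality with ties broken by highest
mean LDA posterior, and reports mean ± SD patient-level balanced accuracy
per group size. Kolmogorov–Smirnov comparisons of individual features are
descriptive; no multiplicity correction is applied.

## The synthetic generator

The generator emulates what the analysis assumes, not the physics of
dielectrophoresis (no Maxwell-stress computation, no hydrodynamics, no
cell–cell interactions — explicit non-goals). A cell is a speckle-textured
disk with a dark membrane ring and a bright defocus halo, rendered at
sub-pixel positions with slowly drifting Gaussian defocus and additive
sensor noise, quantized to 8 bits.

- **Centroid motion.** Per clip, pDEP is a fast relaxation (τ = 0.15 s)
  toward a target displaced toward the active electrode by
  `oscillation_gain` × a linear amplitude profile in frequency (the
  amplitude-vs-frequency law is unpublished; the linear profile is a
  monotone placeholder and a constructor argument), modulated by a damped
  cosine at the 0.2 Hz base rate; near crossover the cell is quasi-static;
  below crossover it drifts slowly away from the electrode axis. A small
  Brownian jitter (0.01 px/frame, configurable) is superimposed.
- **Local deformations.** Smooth Gaussian displacement bumps in the
  centroid frame: six stimulation-locked bumps per clip with a sin²
  temporal envelope, oriented along the electrode axis (bimodal mode,
  80% toward the active electrode) or in antipodal pairs of uniform
  directions (diffuse mode — heterogeneous orientations with near-zero net
  displacement, so the bulk centroid is not dragged); plus Poisson
  off-stimulus events — larger, broader, randomly oriented transient
  bumps at `off_stimulus_event_rate`.
- **Class recipes.** CTRL = bimodal + low event rate; RIF = diffuse + low
  rate; uRPL = diffuse + high rate (0.02 / 0.02 / 1.0 events/s). These are
  minimal sufficient contrasts targeting the two dominant discriminators:
  orientation regularity (kurtosis of θ̄) and deformation regularity
  (approximate entropy of θ̄).
- **Hierarchy and seeding.** One master seed spawns per-patient child
  seeds, each spawning per-cell seeds, so any subset of a cohort
  regenerates bit-identically. Patient- and cell-level parameter draws are
  multiplicative log-normal jitters (σ = `inter_patient_sd`, default 0.1;
  half that at cell level).
- **Ground truth.** The exported per-frame-pair fields are the *apparent*
  displacements in the ROI frame: the deformation increment plus the
  sub-pixel residual of ROI re-centering. This is exactly what a
  displacement estimator sees, and it is what the PIV recovery tests
  compare against.

A deliberate design lesson is recorded here because it shapes the
defaults: because cos θ ignores magnitude, *any* coherent frame-to-frame
translation — however small — saturates θ̄ at ±1. Early generator drafts
with slow relaxation and larger jitter produced orientation series
dominated by re-centering flicker in every class. The defaults therefore
keep quiet phases genuinely quiet (fast relaxation, small jitter,
antipodal diffuse bumps) so that the stimulus-locked structure and the
off-stimulus events, not bookkeeping artifacts, drive the descriptors.
The same saturation mechanism exists for real data; it is a property of
the analysis, not of the simulator.

### What the synthetic tests show — and do not

Passing tests show the chain is internally consistent: the estimator
recovers what the generator injected, the descriptors respond to the
behaviours they are meant to measure, and the selection/validation
machinery neither leaks nor hallucinates class structure (label
permutation sits at chance). They do not show that real endometrial
stromal cells are classifiable: the generator's deformation bumps,
amplitude profile and class contrasts are stylized, its texture is
stationary speckle rather than organelle structure, defocus is a global
blur rather than depth-dependent optics, and effect sizes were chosen to
be clearly expressed at small cohort sizes.

## Problem sizes used in the tests

The reference test cohort is 3 classes × 3 patients × 8 cells (72 cells)
with 0.8 s clips (416 frames), a 9 px cell radius on a 96×160 px canvas
and a 41 px ROI, under master seed 7 — the package's own choice of a
desk-scale configuration that exercises every stage of the full design
(the full-scale default being 6 patients × 30 cells, 1.9 s clips, 151 px
ROIs). On this cohort the LOPO single-cell balanced accuracy is ≈0.8, the
kurtosis and entropy of the orientation series are the most-selected
features, and majority voting saturates by ≈5 cells per patient. The
416-frame window also satisfies the scattering feasibility bound (at
least one period of the 0.06 Hz filter needs ≥ 334 samples at 20 Hz).

## Known limitations

- The substitute tracker handles a single cell near the initial position;
  crossing cells and lost tracks beyond one frame are out of scope.
- The circular-Hough radius floor (accumulator 0.3) is heuristic; on
  featureless frames the pipeline falls back to one third of the ROI side
  and logs it.
- The exact normalization of the approximate-entropy counts and the exact
  scattering path ordering are fixed by this package's own documented
  conventions (the direct-count oracle and the canonical name order);
  other implementations may differ by small constants or permutations.
- Classification assumes every patient carries exactly one class label and
  at least two patients per class are available for nested selection.
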