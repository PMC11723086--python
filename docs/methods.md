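# Methods

## The decay model and its calibration

A kernel's CPMG echo train is modeled as a three-component exponential
mixture

  y(t) = A_f e^{−t/τ_f} + A_m e^{−t/τ_m} + A_s e^{−t/τ_s} + ε,

the three components standing for bound (fast), immobilized (medium) and
free (slow) water. Three components are the most that can be identified
from the published per-variety statistics, which report exactly three
pool fractions. The acquisition grid places echoes at t = k·0.2 ms for
k = 1..3000 (first echo one spacing after excitation, as a CPMG sequence
produces; span 0.2–600 ms). Grid spacing and length are configurable;
the defaults reconcile the published 3000-point raw curve with its
0–600 ms plotting range and contain the largest calibrated cut-off time
(≈562 ms) with margin.

Calibration (`simulate.calibrate_variety`) maps a variety's published
feature means into generator parameters:

* amplitude fractions start at the published pool ratios; τ_f is pinned
  at the log-midpoint of the fast pool window (1 ms);
* (τ_m, τ_s) are solved by 2-D root finding so the noiseless curve
  crosses e⁻¹ of its first-echo value at the published T2 value and the
  cut-off fraction at the published cut-off time;
* a short fixed-point loop then re-targets the amplitude scale, the two
  crossing times, and the fractions against the *actual extractor*
  (including smoothing, discretization and inversion bias), so the
  noiseless round trip lands on the published means to ~10⁻⁶ relative.
  Calibration fails loudly, naming the variety and the worst target, if
  the round trip misses by more than 1%.

Feasibility fixes two defaults that could not be chosen freely. Given a
variety's T2 value and cut-off time, a positive exponential mixture is
log-convex, which bounds from below the signal fraction reachable at the
cut-off time: for all 11 varieties that bound is ≈ 0.04 of the maximum.
The cut-off threshold (the operational stand-in for "decay to 0%", which
noise makes unreachable) is therefore 0.10 of the maximum. The solved
time constants then fall at τ_m ≈ 105–110 ms and τ_s ≈ 440–550 ms for
every variety, so the pool windows are [grid-min, 10) ms (fast),
[10, 250) ms (medium) and [250 ms, grid-max] (slow). Both values are
configuration, not code.

Per-sample variation has three calibrated parts, all derived from the
published per-variety SDs: a common multiplicative amplitude jitter
(relative SD = published max-signal SD / mean), a **common**
multiplicative time-constant jitter (relative SD = published T2-value
SD / mean) — common across pools because crossing times then scale
linearly with the factor, so jitter spreads them without biasing their
means (independent per-pool jitter provably biases the cut-off time
downward via Jensen's inequality) — and additive Gaussian echo noise at
0.3× the published max-signal SD. Magnitude noise at this SNR is
effectively Gaussian; Rician noise is deliberately not modeled.

## Feature extraction conventions

* Savitzky–Golay smoothing with window 11, polynomial order 3 (defaults;
  the feature definitions do not depend on them strongly).
* "37%" is interpreted as exactly e⁻¹, so a mono-exponential curve
  returns its own time constant. Crossings are linearly interpolated
  between bracketing echoes and referenced to the observed (first-echo)
  maximum; consequently every crossing time carries a +0.2 ms offset
  relative to the ideal t=0 reference. Tests assert identities to
  within one echo spacing.
* Curvature κ = |y″|/(1+y′²)^{3/2} is computed on the amplitude-
  normalized curve with time in ms, via `np.gradient` applied twice,
  excluding the first and last samples from the argmax. Near the first
  echo the five-point second-difference stencil places the argmax at the
  third sample (0.6 ms) for every calibrated variety, robustly across
  noise draws and τ_f ∈ [0.5, 4] ms. The convention (normalization,
  units, stencil, exclusion) is fixed in `NMRConfig`; changing any of
  them moves the curvature point, which is why it is configuration.
* The T2 spectrum is solved on 100 log-spaced points in [0.1, 1000] ms
  by NNLS on the λ-augmented design. λ = 0.01 on amplitude-normalized
  curves: small enough that noiseless pool recovery is exact to <1% and
  the reconstruction error is ≪2%, large enough to stabilize the
  inversion at the generator's (high) SNR. λ is fixed rather than
  L-curve-selected so results are deterministic.
* T2 Mean and T2 Std are the mean and population SD of the normalized
  amplitude vector over the acquisition window. This is an operational
  definition: no definition consistent with the published scale of these
  two columns could be derived, so they are excluded from calibration
  targets and carried as ordinary (still discriminative) features.

## Image simulation and measurement

The image generator renders non-overlapping rotated ellipses with
per-variety size, axis ratio, base color and texture noise on a dark
background, returning ground-truth masks alongside. It emulates
controlled acquisition (dark background plate, fixed illumination); it
does not model shadows, specular highlights, germ/endosperm structure,
or camera optics — segmentation results here are easier than on real
photographs.

Segmentation: Otsu threshold (with a minimum-intensity floor so a blank
noisy frame yields nothing), connected-component area filter, Euclidean
distance transform lightly Gaussian-smoothed (σ=2 px, suppressing the
ridge-plateau oversegmentation of elongated blobs), `peak_local_max`
markers, watershed. Perimeter is measured on the marching-squares
contour subsampled every 5 points, which removes the pixel-staircase
bias (a rasterized circle then yields r ≈ 0.99, a square r ≈ 0.79 ≈
π/4). GLCM texture uses 8 grey levels and offsets (0,1),(1,0),
symmetric, averaged, with out-of-mask pixels excluded via a reserved
level; SDs are population (ddof=0) throughout. `a_dev` is the SD of the
RGB red channel — the naming convention of the field this package
follows, despite 'a' usually meaning Lab a*.

The 52-feature roster is 11 geometric + 6 GLCM + 21 histogram bins + 14
color statistics; only {v_mean, s_dev, a_dev, r, E} feed the default
pipeline, and the selection module can re-derive rankings by RFE
(linear max-margin ranker, C=1, step 1), ReliefF (k=10, all samples,
L1 distances on min-max-scaled features) or mutual information
(equal-width 10-bin discretization, reported in bits).

## Fusion, tuning, evaluation

Feature-level fusion (the default, 10+5=15 columns) is lossless column
concatenation with block provenance; decision-level fusion trains one
OAA model per block and averages decision scores. The kernel-to-sample
correspondence the real study leaves implicit is resolved explicitly:
kernels are aggregated per sample by mean (or median), and the synthetic
pipeline renders one kernel per NMR sample aligned via ground-truth
masks. Scaling is z-scoring with statistics from training rows only,
refitted inside each CV fold; zero-variance columns scale by 1 with a
warning.

Tuning minimizes 1 − mean stratified 5-fold CV accuracy over
(log₂C, log₂γ) ∈ [−5,15]×[−15,3] with the HDE optimizer (NP=10, G=15 in
the end-to-end runs — ~160 objective evaluations, each a 5-fold fit,
keeps a full run within a couple of minutes on one CPU; NP=20, G=50 are
the optimizer's general-purpose defaults). The train/validation split is
24/6 per class, stratified and seeded. Evaluation reports the confusion
matrix, accuracy, macro precision/recall/F1, and per-class one-vs-rest
AUC from decision scores.

## The optimizer

Classic DE (mutation, binomial crossover with guaranteed donor index,
greedy selection, reflection at bounds) is recovered exactly with
`adaptation="fixed"` and a single strategy — a property checked against
an independently coded textbook DE, step for step on a seeded run. The
hybrid controls:

* convergence indicator c_t = |f_best(t) − f_best(t−1)| /
  max(|f_best(t−1)|, 1e−12) (window configurable). The piecewise rule
  maps stagnation (small c_t) to conservative F and high CR.
* diversity D = mean pairwise Euclidean distance in bounds-normalized
  coordinates, D_max recorded at initialization; the diversity rule
  shifts F and CR by Δ·(1 − D/D_max).
* the default "combined" mode applies the piecewise rule then adds the
  diversity shift; F and CR are clipped to [0.05, 1].
* the uniform draw r in the piecewise rule is taken **per individual**,
  not per generation. Its stated role is to avoid premature convergence,
  and a shared draw demonstrably fails at that: with one r per
  generation the population occasionally collapses before converging
  (5-D sphere reached 1e−3 in only 93/100 seeded runs, and the adaptive
  variant lost to classic DE on 2-D Rastrigin); with per-individual
  draws step sizes stay heterogeneous and both benchmarks pass cleanly.
* stage boundaries at G/3 and 2G/3 (rand/1, then current-to-best/1,
  then best/1 alternating with best/2), configurable.
* minimization convention; accuracy objectives are negated (as
  1 − accuracy). Non-finite trial evaluations are rejected with a
  warning rather than propagated.

Seeded runs are bit-reproducible; the random-draw order is documented in
the module docstring and relied on by the oracle test.

## Shapley attribution

The attribution target is the per-class OAA decision score — monotone in
the prediction and deterministic, unlike post-hoc probabilities. The
sampler follows the Shapley definition directly: for each sampled
feature ordering a background row is drawn, features flip from
background to instance values in order, and each feature is credited
with the score change it causes; the base value is the mean background
score. An exact enumerator over all 2^n coalitions (n ≤ 12, absent
features at the background mean) serves as the oracle; it satisfies
efficiency exactly, and the sampler matches it to <0.01 at 20 000
permutations on a 5-feature model. Defaults: background = seeded
subsample of ≤100 training rows, 2000 permutations per instance.

## What the synthetic study does and does not show

The generator reproduces the published per-variety *means and
dispersions* of the decay features, and plausible between-variety image
differences. It does not reproduce the real within-variety biological
covariance structure, instrument drift, or segmentation difficulty of
real photographs — the synthetic classes are more cleanly separated than
real seeds, which is why the end-to-end run reaches ~100% validation
accuracy where the real study reports substantially less. Passing tests
therefore demonstrate that the pipeline's machinery is correct and
calibrated, not that these accuracies transfer to real kernels.
Problem sizes in the test suite (330 samples, NP=10/G=15 tuning, 30-seed
optimizer comparisons) are the package's default desk-scale conditions.

## Known limitations

* The three-pool model cannot express multi-modal pools or T2–T1
  correlation; 2-D relaxometry is out of scope.
* Crossing times inherit a one-echo-spacing offset from the first-echo
  reference; calibration absorbs it, but absolute comparisons with
  other instruments' T2 values should account for it.
* The curvature-point location is a convention-dependent quantity (see
  above); treat it as a fingerprint feature, not a physical time scale.
* ReliefF is O(m·n·d) without neighbor indexing — fine at desk scale,
  slow beyond ~10⁴ samples.
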