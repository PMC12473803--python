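# Methods

## Scope and data model

`copbench` analyses center-of-pressure (CoP) trajectories recorded by
pressure-sensing insoles during the Timed Up and Go (TUG) test and
benchmarks their value for separating Parkinson's disease (PD) from
control participants. All coordinates live in the insole's normalized
coordinate system — medio-lateral (ML) axis in [-0.5, 0.5],
anterior-posterior (AP) axis in approximately [-0.574, 0.426], identical
for both feet, dimensionless — sampled uniformly (100 Hz by default).
Features are therefore dimensionless or per-second; no physical-unit
conversion is ever applied.

Two scenarios are analysed per trial: the full TUG recording, and the
walking segment obtained by concatenating the walk-out and walk-back
phases in time order. The junction between the two sub-walks is marked
as a segment break; velocity-type features skip the single bridging
difference, while spectral and diffusion features are computed on the
concatenated signal as-is (the discontinuity is one sample out of
hundreds and is dominated by the averaging in both estimators).

## CoP from raw sensor frames

When 16-sensor force frames are supplied instead of firmware CoP, the
CoP is the force-weighted mean of the sensor positions,
`cop = sum(d_i * F_i) / sum(F_i)`. An all-zero frame is a swing-phase
(no-contact) sample and yields NaN with a contact flag rather than an
error, so whole trials stream through uninterrupted. CoP columns take
precedence over force columns when a file carries both; a flag forces
recomputation. A testing helper distributes a target CoP over the
sensor layout by barycentric weights on the Delaunay triangulation of
the sensor positions, which reproduces the CoP exactly and closes the
loop between the two code paths.

## The synthetic trial generator

No public generative model exists for insole CoP during TUG, so trials
are composed per foot and axis from three parts:

1. **Phase template** (deterministic): a smooth anterior ramp during
   sit-to-stand (AP -0.40 to -0.05 over 2 s), anti-phase stepping
   sinusoids during the walks (AP amplitude 0.25, ML 0.04, an integer
   number of ~0.9 Hz step cycles so phases join continuously), a
   lateral half-sine excursion of 0.12 during the turn whose direction
   is a per-participant draw, and a posterior ramp back over the final
   3 s. Default phase durations are 2/4/2/4/3 s (15 s total), chosen so
   the diffusion and spectral fits are well-posed; no per-phase timing
   statistics were available to calibrate against.
2. **Oscillatory sway**: one tone below 0.5 Hz (0.3 Hz, amplitude
   0.012) and one mid-band tone (1.3 Hz, amplitude 0.020) with random
   phases per foot and axis.
3. **Stochastic sway**: a first-order autoregressive process
   (pole 0.97, innovation SD 0.004) whose innovation variance encodes
   trajectory "complexity".

Between-participant variability is a log-normal multiplier (SD 0.15 on
the log scale) on the sway parts, plus a per-foot log-normal jitter
(SD 0.05) that gives controls a small physiological base asymmetry.

Group contrasts enter *only* as multipliers (`EffectProfile`):
`sway_amplitude_ratio` (default 1.3) scales both sway parts;
`asymmetry_gain` (1.4) additionally scales one randomly lateralized
foot, mimicking unilateral symptom onset; `lowfreq_power_shift` (0.3)
moves that fraction of mid-band oscillatory power below 0.5 Hz;
`complexity_reduction` (0.3) shrinks the AR innovation variance.
`EffectProfile.zero()` makes PD and Control draws identically
distributed, which is the basis of the null-calibration tests. The
defaults emulate the directions reported for PD sway — larger
magnitude, lateralized asymmetry, a low-frequency spectral shift and
reduced complexity — at magnitudes that make cohorts separable but not
trivially so.

What the generator does **not** emulate: heel-strike/toe-off pressure
micro-structure, swing-phase no-contact gaps, tremor harmonics,
freezing episodes, dual-task effects, or any correlation between
demographics and sway. Passing tests therefore demonstrate the
pipeline's statistical integrity (counts, invariances, leakage-freedom,
calibration), not clinical performance on real recordings.

## The 72-feature registry

The per-foot feature set is frozen in a versioned manifest
(`data/feature_manifest.csv`; name, domain, axis, description) and the
count of exactly 72 is enforced at import. The split is 15 positional,
16 dynamic, 20 frequency (10 per axis) and 21 stochastic (7 for ML, AP
and planar each). Aggregated names carry an em-dash suffix
(`—Average` / `—Asymmetry`), giving 144 scenario columns.

Numerical choices, in registry order:

* **Positional** — all features are computed after subtracting the
  per-trajectory mean (removes foot-placement offset). The 95%
  confidence ellipse area is `chi2_95(2) * pi * sqrt(det(cov))` with the
  unbiased covariance; the principal sway direction is the orientation
  of the leading covariance eigenvector in degrees, folded to
  [0, 180). A constant trajectory has zero dispersion and an undefined
  direction (NaN). The planar range is the largest pairwise sample
  distance (convex hull, with a projection fallback for degenerate
  clouds).
* **Dynamic** — velocities are first differences times the sampling
  rate. Peak-velocity features average the positive local maxima
  (respectively negative local minima) of the signed per-axis velocity
  and are 0 when no peaks qualify. Sway area per second accumulates the
  triangle areas swept by the centered position vector. Phase-plane
  parameters combine position and velocity dispersion
  (`sqrt(var(x) + var(v))`). Velocity-based mean frequencies follow the
  classical sway conventions: `MV / (2*pi*MD)` for the resultant and
  `MV / (4*sqrt(2)*MD)` per axis.
* **Frequency** — Welch PSD with a Hann window, segment length
  `min(256, N/2)`, 50% overlap and per-segment constant detrend; the
  parameters travel with each `SpectralEstimate`. The DC bin is
  excluded. Band energies use the partition at or below 0.5 Hz /
  0.5–2 Hz / above 2 Hz and are reported as fractions of total power
  (they sum to 1 by construction). The frequency quotient is the
  above-2-Hz to at-or-below-0.5-Hz power ratio. A total power at the
  floating-rounding floor (<= 1e-20) is treated as a constant signal:
  total power 0 and NaN for the ratio-type descriptors.
* **Stochastic** — mean squared displacement (MSD) over lags up to
  2.5 s; ordinary least squares on MSD vs lag in a short-term window
  (0.02–0.3 s) and a long-term window (1.0–2.5 s), both
  config-exposed. Diffusion coefficients are slope/2 per axis and
  slope/4 for the planar sum; the critical point is the intersection of
  the two fitted lines (NaN when they do not cross at a positive lag,
  i.e. no saturation). Scaling exponents H are half the log–log slope
  in each window and the fractal dimension is `2 - H_short`. The
  feasibility precondition is that the series be longer than the
  long-window lag: both the 15 s full TUG and the 8 s walking segment
  qualify; shorter inputs mark the family missing.

Missing values are NaN plus a per-feature reason recorded by
`extract_all`; downstream aggregation propagates them.

## Bilateral aggregation

Per feature, the scenario value pair is the arithmetic mean
`(L + R) / 2` and the asymmetry index `|L - R| / (|L| + |R|)`, bounded
in [0, 1]. The absolute form is used because signed features (e.g. the
principal sway direction) can make a signed denominator vanish; the
signed variant `(L - R)/(L + R)` remains available behind a flag for
sensitivity analyses. Both sides exactly zero is perfect symmetry at
null magnitude (index 0); a denominator below 1e-12 with unequal sides
is floating noise and reported missing. When a participant contributes
several trials, feature values are averaged across trials before
modelling; this is a package choice (the alternative — picking one
trial — is not exposed because averaging dominates it for stability).

## Density mapping

Occupancy maps pool all CoP samples of one (group, foot) stratum and
evaluate an axis-aligned Gaussian KDE exactly on a fixed lattice
(default 200 x 200 over the full normalized ranges): with a diagonal
bandwidth the kernel sum factorizes, so the surface is one matrix
product rather than a binned approximation. A comparison set shares a
single bandwidth — per-axis Scott's rule `n**(-1/6) * sd` evaluated
once on a reference stratum (Control left by default) and then frozen —
and a single grid, making panels directly comparable by construction.
The numerical integral over the grid is ~1, short only of the kernel
mass truncated at the domain edges.

## Classification protocol

One participant-level, group-stratified 80/20 split (seeded) is reused
by every model; 77 participants yield a 16-subject held-out set. Five
families run with fixed hyperparameters: SVM with RBF kernel (C=1,
gamma="scale", balanced class weights, probability outputs, seed 42),
logistic regression (lbfgs, 2000 iterations, balanced, seed 42), random
forest (100 trees, balanced, seed 42), k-NN (5 neighbours, uniform,
Euclidean) and Gaussian naive Bayes (variance smoothing 1e-9). PD is
the positive class.

Feature selection is greedy sequential forward selection scored by
mean F1 over a stratified 5-fold inner cross-validation (seed 42) of
the training set. One greedy pass grows the subset to the largest grid
size; the per-size scores along the path form the selection curve and
the chosen `k` maximizes the mean inner-CV F1, with ties broken toward
smaller `k` and ties in greedy gain broken by column (registry) order.
Median imputation is fitted on fold-training rows only; z-scoring is
applied within the same discipline for the scale-sensitive families
(SVM, LR, k-NN) and skipped for RF and NB. After fixing the subset the
pipeline is refitted on the full training set and evaluated exactly
once on the untouched test set; ROC-AUC uses class-1 probabilities
(decision-function values would be the fallback for a model without
probabilities). The consensus report tallies which features were
retained by at least a threshold number of models (default 3).

## Problem sizes in the test suite

The calibration suites run the full protocol at the study scale
(39 PD / 38 Control) but with reduced selection problem sizes so the
suite completes on a single CPU: the null-effect suite (20 seeded
cohorts, all five families) selects from a fixed 18-column subsample of
the 144 features (every 8th column, spanning all domains and both
aggregation kinds) with k in {1, 2} — chance-level accuracy on
effect-free cohorts is a property of the leakage-safe protocol and is
insensitive to the candidate-pool size — and the strong-effect suite
(10 seeded cohorts) runs logistic regression on all 144 columns with k
up to 8. Monte-Carlo checks use 100 replicates (Brownian diffusion
recovery) and 10 000 points (confidence-ellipse closed form).

## Known limitations

* The simulator is a statistical emulator, not a biomechanical model;
  absolute feature values are not comparable to real insole data.
* Spectral features are computed on the raw (phase-template-bearing)
  signal, so walking-band template power mixes with sway power; group
  contrasts in the frequency family are correspondingly conservative.
* The walking scenario concatenates sub-walks without a gap model
  beyond the velocity-bridge exclusion.
* The critical point of the diffusion fit is undefined (NaN) for
  non-saturating trajectories such as pure Brownian input; consumers
  must expect missingness there.
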