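# Methods notes

This note documents the models, estimators, parameter choices, and known
limitations of `assrconn`, in the order the pipeline runs them.

## Normalized 40 Hz ASSR power

**Model.** The auditory steady-state response is modeled as a 40 Hz
component with phase fixed across trials (steady-state entrainment),
embedded in trial-independent background activity.  DSS finds the spatial
filter maximizing the ratio of evoked (trial-averaged) to total power; we
whiten by the total second-moment matrix (eigendecomposition, discarding
eigenvalues below 1e-10 of the largest) and eigendecompose the whitened
evoked second moment.  Reliabilities are clipped to [0, 1], sorted
non-increasing with stable tie order; unmixing rows are unit-norm;
forward patterns are the pseudo-inverse of the unmixing matrix; eigenvector
signs are fixed so each component's largest-magnitude pattern weight is
positive.  Raw second moments (no demeaning) are used so that identical
trials give reliability exactly 1.

**Preprocessing.** Average reference, then a zero-phase 4th-order
Butterworth high-pass at 0.8 Hz, then per-trial linear detrend.  The
high-pass is applied to the trials concatenated in recording order: a
0.8 Hz filter needs on the order of a second to settle, so filtering
375 ms epochs individually is dominated by edge transients (we measured
component-recovery correlations dropping from ~0.999 to 0.73–0.93 when
filtering per epoch).  Filtering the concatenation emulates the usual
practice of filtering the continuous recording before epoching.

**Spectral estimator.** The statistic needs 1 Hz background bands with
0.5 Hz guard bands around 40 Hz, i.e. sub-hertz resolution.  A single
375 ms trial has 2.67 Hz native resolution, and zero-padding does not
help: the rectangular window's sinc main lobe (first null at 2.67 Hz)
leaks the component's own energy into the flanking bands, and the ratio
saturates near 1.7 independent of signal strength.  We therefore compute
one periodogram of the *concatenated* single-trial component time courses
(28.125 s for the default 75 x 375 ms protocol).  Because the stimulation
frequency has an integer number of cycles per trial (15), the component is
phase-continuous across the concatenation and confines to a single bin
(width 1/28.125 s ≈ 0.0356 Hz), while background activity fills all bins.
`pad_to_s` (default 4 s) acts only as a resolution floor for very short
recordings.  Power is normalized so the one-sided spectrum satisfies
Parseval's identity exactly.

Raw power is the bin nearest 40 Hz; background power averages bins in
[38.5, 39.5) ∪ (40.5, 41.5] Hz (half-open at the guard edges); the
normalized power is their ratio, on linear power (not log).  Only the most
reliable DSS component feeds the statistic by default (`k` configurable;
with k > 1 per-component periodograms are averaged).

**Precision.** For a single record of length T with background bandwidth
W = 2 Hz, the background estimate averages ~TW independent spectral bins;
at T = 28.125 s its coefficient of variation is ~13%, and the coherent
40 Hz bin adds ~2/sqrt(ratio).  This irreducible measurement noise is why
the end-to-end synthetic study uses an encoding gain (below).

## Synthetic EEG

75 trials x 375 ms x 1000 Hz x 64 channels by default (tests use fewer
channels).  The 40 Hz component is a sinusoid — the analysis reads only
the 40 Hz bin, so click-train harmonics are irrelevant — with a
deterministic unit-norm scalp topography and a seeded random phase shared
by all trials.  `snr` is the component amplitude at the best channel
divided by the noise RMS there (noise normalized to unit RMS per channel).
Background noise is 1/f-shaped (exponent 1 by default) per source,
spatially mixed by I + 0.5 G/sqrt(C) with G standard normal — a
well-conditioned random "volume conduction" matrix.  The noise stream is
drawn before any signal parameter is used, so recordings with different
snr but the same seed share the identical noise realization; tests exploit
this to decompose any recording exactly into signal and noise.
`mixing_seed` optionally fixes the mixing across recordings (one head
geometry for a whole cohort).

## Synthetic fMRI

Grid 24 x 24 x 16 at 4 mm (desk-scale but large enough for cluster
inference), TR 2 s, 444 volumes.  ROI spheres share latent unit-variance
signals drawn with a configurable target correlation matrix (validated
symmetric, unit-diagonal, positive semidefinite; a nearest-PSD projection
helper repairs mildly indefinite targets built from noisy Fisher-z
values).  Within-ROI voxel noise is re-centered so the ROI mean equals the
latent exactly — ROI-mean correlation estimates then converge to the
target as frames grow, with no attenuation bias.  Background voxels carry
Gaussian noise smoothed at 4 mm FWHM (the volumes emulate already-smoothed
data).  WM is an outer shell and CSF a bottom slab, both disjoint from the
ROIs, each carrying its own slow nuisance signal.  Motion is a small
random walk (per-step sd 0.02 mm translation, 2e-4 rad rotation) with
persistent translation jumps at spike frames so approximately
`motion_spike_rate` of frames exceed the 0.2 mm censoring threshold.

What the generator does **not** emulate: scanner physics, physiological
noise spectra, spatial anatomy, registration error, and spatially
structured artifacts.  Passing tests show the estimators are correct under
the stated statistical structure, not that they are robust to real-scanner
pathologies.

## Synthetic cohort (mediation ground truth)

Linear structural model per subject: M_j = α_j + a_j X + κ_j Age + ε_j;
Y = β + c′ X + Σ b_j M_j + γ Age + ε_Y, with X the diagnosis indicator
(SZ = 1), independent mediator noises, ages truncated-normal on [18, 65]
with group means/SDs 33.92/12.80 (SZ) and 35.58/13.98 (HC), and sex drawn
at the 44:22 / 51:34 group ratios.  Defaults encode full mediation:
c′ = 0; seven mediators in Fisher-z units (α = 0.35, noise sd 0.2) of
which three are strong (a = −0.15, b = 10) and four weak (a = −0.04,
b = 5), giving a planted indirect total of −5.3.  The intercept is solved
in closed form so the healthy-group population mean of Y equals 81.52, and
the outcome noise is derived from the target within-group SD (12.4); with
those choices the SZ population mean lands near 76.2.  `population_moments`
returns the exact per-group mean and variance for oracle checks.  With
n = 151 the population-level total-effect t is ≈ 2.5, so any *single*
cohort draw has an appreciable chance of a non-significant total effect;
statements about significance rates are therefore always made over
replicate cohorts.

Mediator noises are independent across circuits.  Real rsFC circuits
sharing nodes are correlated; with independent mediators the seven
marginal mediator-outcome correlations cannot all be as large as observed
in real data (the implied R² would exceed 1), so within-group
circuit–ASSR correlations are weaker here than in a comparable real
cohort.  This limits rule-2 candidate detection at the default effect
sizes; the candidate machinery is exercised with purpose-built tables.

## rsFC estimators

Framewise displacement is the Euclidean norm of the frame-to-frame
translation plus the rotation converted to arc length on a 50 mm sphere;
"neighboring time points" means exactly one frame on each side of a
supra-threshold frame.  The nuisance design is [intercept, linear trend,
6 motion parameters, their 6 backward differences, WM mean, CSF mean],
with the trend built from the retained frames' original indices so that
censor-then-regress equals regression restricted to the retained frames;
the design is rejected above condition number 1e8.  WM/CSF regressors are
global tissue means (not locally averaged).  Sphere membership is by
voxel-center Euclidean distance in mm through the affine.  Zero-variance
voxels receive r = 0 with a degeneracy flag so maps stay finite;
correlations are clipped to ±(1 − 1e-7) before atanh, so self-correlation
circuits yield a large finite z rather than infinity; transforming an
already-z map raises.

## Screen

Group is coded SZ = 1, and ASSR is mean-centered before forming the
interaction so the main effect is interpretable at the average group mix.
F statistics for the ASSR and interaction terms come from nested-model
residual sums of squares (single-coefficient F = t²).

**Smoothness.** From standardized residual maps, the variance of spatial
first differences gives the lag-1 autocorrelation ρ₁ = 1 − var(diff)/2 per
axis; the smoothing-kernel sigma is recovered by numerically inverting the
*sampled* Gaussian-kernel autocorrelation (a lookup/brentq inversion, so
the estimator is exactly consistent with the package's own
`gaussian_filter`-based field simulator).  Reported FWHM includes the
one-voxel sampling contribution in quadrature — unsmoothed white noise
reports one voxel — and generator metadata records the same effective
convention, `sqrt(kernel_fwhm² + voxel²)`.

**Cluster extent.** Null fields are Gaussian with a single Gaussian ACF
(the mixed Gaussian+exponential ACF of newer tools is out of scope),
thresholded two-sided by default (matching F with one numerator df),
clustered by face adjacency (6-connectivity).  The extent threshold is the
smallest size s with empirical P(max null cluster ≥ s) ≤ α.  Because
cluster sizes are integers this rule alone is conservative (we measured
family-wise rates near 0.03 at α = 0.05 on this grid); by default the
threshold is therefore *dithered* between the two bracketing integers with
the mixing probability that makes the expected family-wise rate exactly α.
`dither=False` restores the strictly conservative integer rule.  Within
each screen, flagged clusters always satisfy size ≥ that screen's
threshold.

**Candidates.** Rule 1: significant ASSR x Group interaction for the
circuit value.  Rule 2: within-group Pearson associations significant and
same-signed in both groups, plus a group difference surviving BH-FDR over
the circuit family and pointing the deficit way (weaker in patients when
the association is positive).  FDR families follow the screening seed
(one family per seed's cluster set).

## Mediation

All three regressions share the covariate set, so c = c′ + Σ a_j b_j holds
to machine precision.  Bootstrap CIs are percentile (BCa is deliberately
not the default; the percentile interval is the simplest choice consistent
with a generic "bootstrap CI"), with subjects resampled unstratified by
default (a stratified option exists).  The full resample index block is
drawn up front from one seeded generator, so results are bit-reproducible
and independent of execution order; resamples that cannot identify the
model — one diagnostic group only, or a rank-deficient design from too few
distinct subjects — are redrawn (random mode) or excluded (exhaustive
mode), with the redraw count reported.  Exhaustive mode (n ≤ 8) evaluates
all n^n resamples in chunks and yields exact percentile endpoints; the
test suite verifies them against an independently coded closed-form
enumeration.  Mediators enter in raw Fisher-z units (no standardization).

## End-to-end synthetic study (`run_all`)

The orchestrated run draws a cohort, then *encodes* each subject's
assigned quantities into raw signals and re-measures them:

* EEG: snr² is affine in the assigned normalized power, anchored so the
  healthy-group mean maps to snr_ref = 2 (where DSS recovery is reliable),
  with a contrast gain (default 2.5) expanding between-subject differences
  so the ~13% background-estimation noise of a single record does not
  swamp the cohort's ~16% relative spread.  The measured normalized power
  is therefore an approximately linear, low-noise transform of the planted
  value *on its own scale*; printed-scale calibration (76.23/81.52) is the
  cohort generator's job, not the signal chain's.  One mixing matrix
  (head geometry) is shared across subjects.
* fMRI: node spheres are placed deterministically on a lattice; each
  subject's ROI correlation targets are tanh of the planted circuit z
  values (baseline 0.1 elsewhere), PSD-projected if needed.  Circuits are
  re-measured after trimming, censoring, and nuisance regression, and one
  seed's z-map per subject feeds the voxel-wise screen.
* Screening and mediation then run on the *measured* table.

Stage seeds are spawned from the master seed and recorded in
`provenance.json`; reruns are byte-identical.

## Problem sizes

Defaults mirror the emulated study (75 trials, 64 channels, 444 volumes,
66 + 85 subjects, B = 10,000, n_null = 1000).  The test suite and the
acceptance script use reduced sizes chosen for desk-scale runs — fewer
channels (6–8), shorter scans (80–200 volumes), B = 200–2000,
n_null = 120–300, and 20–500 Monte Carlo replicates — sizes at which the
checked properties are already statistically decisive.

## Known limitations

* The spectral background of a single 28 s record has ~13% estimation
  noise; cohort-scale normalized powers cannot be reproduced through the
  raw-EEG chain without the encoding gain described above.
* Null cluster fields use a pure Gaussian ACF; heavy-tailed spatial
  autocorrelation in real BOLD data would make the extent threshold
  anti-conservative.
* Smoothness estimation assumes stationary isotropic smoothing on a
  regular grid.
* The mediation model is linear with no X x M interactions and no
  latent-variable measurement model; bootstrap CIs are percentile, which
  can undercover slightly at small n.
* Independent mediator noises understate the correlation structure of
  real circuit families (see the cohort section).
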