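# Methods

This note documents the models, conventions and numerical choices behind
`imdec`, and what the synthetic-data tests do and do not establish.

## Paradigm and forward model

The simulated session mirrors a four-direction motion-imagery block
design: each run opens with a 12 s rest, then ten blocks of four
consecutive trials (one per direction, randomly ordered within the
block), separated by rests of 8, 10 or 12 s.  Trials last 6 or 8 s.
Four runs give 160 trials, 40 per direction.  All durations are integer
multiples of the TR (2 s), so trial onsets align to the volume grid.
Where the task description leaves a distribution open — how 6 s versus
8 s trials are assigned, and which rest duration follows a block — the
draws are equiprobable and seeded; rating-scale periods of the real task
carry no modelled signal and are folded into the rests.  Every random
component (event ordering, BOLD noise, gaze, label scrambling) draws
from a named substream of one master seed, so stages are reproducible
independently of each other.

The BOLD forward model is deliberately the same linear model the
analysis assumes: voxel $v$'s signal is

baseline + Σ_c a(c, v) · (boxcar_c ∗ h) + d·cos(2πt/T_run) + ε,

with $h$ the canonical two-gamma HRF (response delay 6 s, undershoot
delay 16 s, unit dispersions, peak:undershoot ratio 6, peak-normalised;
these parameters are configurable), convolution restarting at run
boundaries, one cosine cycle of drift per run, and iid Gaussian noise.
Defaults: baseline 100, noise SD 1, drift amplitude 2 (the drift lies
below the 2-cycle high-pass band, so the filter has something real to
remove), informative amplitudes around 1.5–3 signal units ≈ 1.5–3% of
baseline.  The simulator therefore emulates direction-selective
responses, run offsets and slow drift; it does **not** emulate temporal
autocorrelation of physiological noise, motion, distortion, spatial
noise correlations, or hemodynamic nonlinearity.  Passing tests show the
pipeline is correct and calibrated under its own assumptions — not that
real 7 T data would yield the same accuracies.

ROI dilation adds all face-adjacent (6-connected) neighbours of the mask
per fold of dilation, the volumetric analog of adding boundary vertices
to a surface patch; surface reconstruction itself is out of scope.

## Preprocessing

Order: high-pass filter → z-score → trial extraction.

- High-pass: per run and voxel, OLS on [intercept, linear trend,
  sine/cosine at 1 and 2 cycles per run]; output is residuals plus the
  run mean.  Runs must hold at least twice the basis size (12 volumes).
- Z-scoring uses the population (N) standard deviation per voxel per
  run; constant voxels map to zeros and are flagged rather than raising.
- Features: mean of the volumes whose onset-relative time lies in the
  half-open window [4, 10) s — exactly the 3 volumes at 4, 6, 8 s for a
  2 s TR.  Off-grid onsets (impossible under the default paradigm) are
  rounded to the nearest volume.

## Decoding

Leave-one-run-out cross-validation, one fold per run.  Within each fold
the one-way ANOVA F (between/within class variance ratio over the four
directions) is computed on the training trials only and the k = 1000
highest-F voxels are retained; infinite F (zero within-class variance)
ranks above all finite values and ties at the cutoff break by ascending
voxel index, making selection deterministic.  Classification is
one-vs-one: six binary linear soft-margin SVMs (regularisation C = 1 by
default; the underlying binary learner is libsvm's linear SVC) with
majority voting; vote ties go to the lowest class label.

The permutation test reruns the *entire* fold-wise pipeline (selection
included) under scrambled labels and uses the add-one estimator
p = (1 + #{null ≥ observed})/(n_perm + 1), which cannot return zero.
Two scrambling schemes are provided.  The default scrambles labels
globally across all trials (preserving total class counts).  The
`within_run` scheme permutes labels within each run, preserving the
paradigm's run-balanced label multisets; it is the exactly exchangeable
null for this design, under which the p-value is discrete-uniform, and
it is what the calibration suites use.  At full scale (40 trials per
condition per session) the two schemes are practically indistinguishable;
at very small trial counts global scrambling can additionally produce
runs missing a class, which the cross-validation contract rejects.

Expected behaviour under no signal: with runs balanced by design, the
mean cross-validated accuracy is an unbiased estimate of chance (25%) —
the class-symmetry argument requires balanced training folds, which the
paradigm guarantees.

## Group statistics

Subject counts in this setting are small (a dozen), so the Wilcoxon
signed-rank test (per-subject real accuracy vs mean permutation
accuracy) and the Mann–Whitney U test (between subject groups) use
exact enumeration p-values: a dynamic program over doubled (hence
integer, tie-tolerant) ranks for Wilcoxon, and enumeration of group
assignments for U.  Zero differences are dropped before ranking
(Wilcoxon's original treatment); W is the smaller signed-rank sum, U
the smaller group statistic; two-sided p = 2·min(lower tail, upper
tail), capped at 1.  Note that exact and asymptotic p-values differ
noticeably at n = 12: a uniformly positive sample gives exact
p = 2/4096 ≈ .0005 where the normal approximation reports ≈ .002.
The implementation reports the exact value; scipy's asymptotic versions
serve as cross-checks in the tests.  Spearman correlations with
questionnaire scales are BH-FDR-adjusted across the three scales.

## Searchlight

Sphere membership is every integer offset with Euclidean norm ≤ r in
voxel units, boundary inclusive — the convention that uniquely yields
257 voxels at r = 4.  Only the center must lie in the ribbon mask;
members are any in-volume voxels (a strict mode restricts members to
the ribbon too), and spheres clip at volume borders.  Per center the
standard pipeline runs with no feature selection and no permutation
test; the pooled confusion matrix over folds feeds a Pearson chi-square
test of true × predicted independence (df = 9; expected counts from the
margins; an all-zero predicted column contributes nothing, since a class
that is never predicted is legitimate classifier behaviour, whereas an
all-zero true row is an error).  Center p-values are BH-FDR thresholded
at q = 0.05.  An optional connected-component minimum-size filter
(6-connectivity, off by default) stands in for surface cluster
thresholding, which has no volumetric equivalent here.

## Univariate analysis

The GLM design holds one HRF-convolved boxcar per direction plus per-run
intercepts and optional per-run linear drifts; convolution is at TR
resolution (all paradigm times are TR multiples, so oversampling adds
nothing).  Per-voxel OLS gives betas, residual variance and dof; the
one-vs-all contrast is +1 on the preferred direction and −1/3 on the
others, so a non-selective voxel has t ≈ 0.  T-maps are two-sided
FDR-thresholded at q = 0.05.  The preference map takes the argmax over
the four one-vs-all t-maps inside the searchlight significance mask,
ties to the lowest label; the same single GLM feeds both the thresholded
t-maps and the preference map.  No autocorrelation model is fitted.

## Eye tracking

Blink rejection discards samples whose pupil aspect ratio leaves the
per-trial mean ± 2 SD interval.  Saccade detection follows the standard
velocity-threshold scheme: 5-sample moving-window velocities, per-axis
robust SD σ = √(median(v²) − median(v)²), elliptic criterion
(v_x/λσ_x)² + (v_y/λσ_y)² > 1 sustained for ≥ 3 samples, with λ = 6;
direction is the atan2 of the net displacement.  The sampling rate is
configurable (default 60 Hz, typical of MR-compatible trackers); the
detector's λ and minimum duration are the canonical defaults.

Direction comparisons use Fisher's common-median test (counts per group
on either side of the pooled circular median; the P statistic is
asymptotically chi-square with groups − 1 df — accurate from roughly 30
angles per group, mildly anticonservative below) and the
Jammalamadaka–SenGupta circular–circular correlation with its
large-sample normal p-value.  One caveat the tests make explicit: with
a perfectly balanced four-direction design the circular mean direction
is ill-defined (vanishing resultant), which destabilises the
correlation estimate; calibration and recovery checks therefore use
designs with a non-vanishing resultant.

Per-trial gaze ellipses are minimum-volume enclosing ellipses fitted by
Khachiyan's reweighting algorithm (tolerance 1e-4 on the weight change,
then a minimal rescale so every point is contained).  Ellipse rotation
is axial (a line, 180°-periodic), so rotations are doubled before the
circular tests and results are reported on the doubled scale.

## Problem sizes used in tests and the acceptance script

All test data are generated at run time.  The chance-calibration suite
uses 50 pure-noise sessions with the full default paradigm on a
144-voxel grid (mean accuracy against the pooled binomial interval) and
100 reduced sessions (3 runs × 4 blocks, 16 voxels, 99 permutations)
for p-value calibration; signal-recovery suites implant 8–16
direction-coding voxels at 3× the noise SD.  The acceptance script
reports the grand mean accuracy over 50 pure-noise default-paradigm
sessions (8000 pooled test trials) with 100 selected features on a
6×6×4 grid.  These sizes were chosen once as desk-scale versions of the
study conditions; the statistical contracts (binomial intervals,
exactness of enumerations) do not depend on them.

## Known limitations

- The simulator's noise is white; real BOLD noise is autocorrelated and
  spatially structured, so real-data accuracies and permutation nulls
  will be wider than the synthetic ones.
- The searchlight ribbon is an arbitrary volumetric mask; the anatomical
  −1 mm…+3 mm cortical-ribbon construction and all surface-based steps
  (reconstruction, projection, surface cluster thresholding) are out of
  scope.
- The SVM regularisation constant is fixed (C = 1) rather than tuned;
  nested cross-validation would be required for tuning without leakage.
- Saccade detection assumes uniform sampling within a trial; blink
  removal leaves gaps that are treated as contiguous.
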