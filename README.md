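# imdec — decoding the direction of imagined visual motion from fMRI

`imdec` reimplements, as a tested Python package, a complete analysis for
decoding *which* direction of visual motion a subject is imagining from
high-resolution BOLD fMRI.  It is aimed at researchers who want to study,
validate or extend this class of mental-imagery decoding pipelines without
access to raw 7 T data: every stage can be exercised end to end on
synthetic sessions with known ground truth.

The pipeline covers:

- **Paradigm & data simulation** (`imdec.paradigm`, `imdec.synth`) — a
  block design of four imagined directions (4 runs x 10 blocks x 4
  trials; 6 or 8 s trials, jittered 8/10/12 s rests; 160 trials, 40 per
  direction), direction-selective voxel responses convolved with a
  canonical two-gamma HRF, per-run cosine drift, Gaussian noise, ROI
  masks with n-fold face-adjacent dilation, and gaze traces with
  optional direction-locked saccades and blinks.
- **Preprocessing** (`imdec.preprocess`) — GLM Fourier high-pass filter
  (2 cycles/run sine+cosine plus linear trend), per-run z-scoring, and
  trial features as the average of the 3 volumes acquired 4–10 s after
  trial onset.
- **MVPA decoding** (`imdec.decode`) — fold-wise ANOVA-F selection of the
  top k = 1000 voxels, one-vs-one 4-class classification with six binary
  linear SVMs and majority voting, leave-one-run-out cross-validation,
  and a scrambled-label permutation test (1000 repetitions of the full
  pipeline) with the add-one Monte-Carlo p-value.
- **Group statistics** (`imdec.group_stats`) — exact Wilcoxon
  signed-rank and Mann–Whitney U tests (enumeration, not asymptotics)
  and Spearman correlations with Benjamini–Hochberg FDR.
- **Searchlight mapping** (`imdec.searchlight`) — a radius-4 sphere (257
  voxels) swept over a ribbon mask, per-center decoding without feature
  selection, chi-square tests of the confusion matrices, FDR
  thresholding.
- **Univariate GLM** (`imdec.univariate`) — two-gamma HRF design,
  voxel-wise OLS, one-vs-all direction contrasts, FDR-thresholded
  t-maps, and direction preference maps masked by searchlight
  significance.
- **Eye-movement controls** (`imdec.eyetrack`) — pupil-based blink
  rejection, velocity-threshold saccade detection, Fisher's common-median
  test and circular–circular correlation of saccade directions, and
  minimum-volume enclosing ellipses of per-trial gaze.

## The model in brief

Trial features are $x_{tv}$, the mean z-scored signal of voxel $v$ in the
window $[4, 10)$ s after trial $t$'s onset.  Within each cross-validation
fold the voxels with the largest one-way ANOVA statistic

$$F_v = \frac{\text{SS}_\text{between}/(C-1)}{\text{SS}_\text{within}/(N-C)}$$

on the training runs are kept, and $\binom{4}{2}=6$ linear soft-margin
SVMs vote on each held-out trial.  Significance is assessed against the
empirical null distribution of mean accuracies under label scrambling,
$p = (1 + \#\{A^\text{null} \ge A^\text{obs}\})/(n_\text{perm} + 1)$,
with chance at 25%.

## Worked example

```python
import numpy as np
from imdec import (ParadigmSpec, GroundTruth, DirectionDecoder,
                   generate_events, generate_bold, preprocess_and_extract)

spec = ParadigmSpec(seed=41)           # 4 runs x 10 blocks x 4 trials
events = generate_events(spec)
shape = (4, 4, 3)
informative = np.column_stack(np.unravel_index(np.arange(16), shape))
amp = np.zeros((4, 16))
for v in range(16):                    # voxel v codes direction v % 4 + 1
    amp[v % 4, v] = 3.0
truth = GroundTruth(informative_voxels=informative, amplitude_matrix=amp,
                    noise_sd=1.0, drift_amplitude=2.0, seed=42)
bold = generate_bold(events, truth, shape, spec)
features = preprocess_and_extract(bold, events)
result = DirectionDecoder(features, n_features=24).fit(n_perm=99, seed=7)
print(result.summary())
```

prints

```
Leave-one-run-out decoding
  folds (held-out runs):   [1, 2, 3, 4]
  fold accuracies:         1.000, 1.000, 1.000, 1.000
  mean accuracy:           1.0000
  chance level:            0.2500
  pooled trials:           160
  permutations:            99
  null mean accuracy:      0.2384
  null 95th percentile:    0.2944
  p (add-one Monte Carlo): 0.01
```

With 16 voxels coding the four directions at three times the noise SD,
the decoder recovers the implanted code perfectly while the scrambled-
label null stays at chance (mean 0.238); the permutation p equals its
minimum attainable value 1/(99+1), i.e. the observed accuracy beat
every scrambled-label rerun.

A command-line interface mirrors the stages:

```bash
imdec simulate --seed 1 --out session/
imdec decode --events session/events.tsv --bold session/bold_run-*.nii \
             --k 100 --n-perm 1000 --seed 1 --out result.json
imdec searchlight --events session/events.tsv --bold session/bold_run-*.nii \
                  --ribbon session/roi.nii --radius 4 --out maps/
imdec eyetrack --gaze session/gaze.csv --out eye/
```

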