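# driftgaze

Drift-diffusion modelling of dual-saccade target selection: does what you
are currently looking at change where you look next?

## The problem

In the paradigm this package analyses, observers make two saccades per
trial: the first acquires a predetermined *inspection target* — either a
face or a phase-scrambled noise patch, either previewed peripherally or
hidden behind an outline until fixated — and the second chooses freely
between two peripheral *selection targets* (always one face, one noise
patch). Each trial yields one binary choice (face vs noise) and one
*fixation duration*, the time spent on the inspection target before the
choice saccade. The scientific question is whether foveal inspection and
peripheral preview merely delay the next saccade or interfere with the
selection decision itself.

## The model

Choice and fixation duration are modelled jointly as the first passage of
a Wiener diffusion between two absorbing boundaries (upper = saccade to
the face, lower = to the noise patch):

- `a` — boundary separation, `zr` — relative starting point,
- `v` — mean drift rate (evidence/s; positive favours the face),
- `t0` — mean non-decision time (s),
- `sv, sz, st0` — across-trial variability of drift (normal SD),
  starting point and non-decision time (uniform widths).

A family of eight variants frees `v`, `a`, `t0` — or any combination —
across the four conditions (inspection identity x preview: FP, FO, NP,
NO); `zr` and the variability components are always shared. Each variant
is fitted per participant by minimising the trial-weighted sum of
per-condition Kolmogorov–Smirnov distances between the empirical and
predicted *signed* response-time distributions (`+RT` for face choices,
`-RT` for noise choices). Variants are compared with BIC information
weights `w_i = exp(-dBIC_i/2) / sum_j exp(-dBIC_j/2)`.

Two further layers complete the analysis: SMART smoothed response time
courses (per-participant Gaussian-kernel smoothing of choice outcome over
fixation duration, weighted group aggregation, cluster-based permutation
tests), and repeated-measures group statistics (all-two-level within
designs computed by exact paired contrasts, `F = t^2`).

A synthetic-experiment generator reproduces the study design — 36
participants, 2x2 within design, 256 trials/condition, 128 stimuli per
category counterbalanced over inspection and selection roles — with
diffusion truth taken from the fitted group means, so the whole pipeline
is testable without any data download.

## Worked example

```python
from driftgaze import SaccadeDDM, FitOptions, SyntheticConfig, generate_session

session = generate_session(SyntheticConfig(n_participants=6, seed=1))
model = SaccadeDDM(session, options=FitOptions(seed=1))
family = model.fit_family()
print(family.summary())
```

prints:

```
DDM family fit, 6 participants
mean information weights:
v+t0     0.514
v+a+t0   0.173
t0       0.165
v+a      0.144
v        0.004
none     0.000
a+t0     0.000
a        0.000
selected variant: v+t0 (k = 13)
```

The `v+t0` variant — drift rate *and* non-decision time free across
conditions — carries the highest mean information weight: foveal
inspection both delays the next decision and biases it. The per-condition
estimates show the generating pattern (drift highest for face/preview,
non-decision time highest for the face/outline conditions):

```python
res = family.results_for(("v", "t0"))
print(res.condition_means())
#                v          t0           a
#             mean   sem  mean   sem  mean   sem
# condition
# FP         0.445 0.370 0.246 0.046 1.030 0.057
# FO         0.181 0.559 0.253 0.044 1.030 0.057
# NP        -0.245 0.298 0.207 0.045 1.030 0.057
# NO        -0.085 0.496 0.215 0.038 1.030 0.057
report = res.parameter_effects()
print(report.summary())        # 2x2 ANOVAs, drift-vs-zero t tests
```

The time-course side:

```python
from driftgaze import SmartTimecourse, SmartConfig
res = SmartTimecourse(session, "preview_within_face", SmartConfig(seed=1)).fit()
print(res.summary())
# SMART comparison over [100, 750] ms, 6 participants, t_crit = 443.46
#   cluster 192-213 ms, t = 58.72, p = 0.847
#   cluster 726-750 ms, t = 83.52, p = 0.723
```

A cluster is a contiguous run of time points whose weighted paired t
statistic exceeds the pointwise threshold; its strength (summed |t|) is
compared against the 95th percentile of 1000 within-participant
permutation maxima (`t_crit`). At this demonstration scale (6
participants) neither cluster clears `t_crit` — condition time-course
differences of the generated effect size need larger cohorts.

The same workflow is available from the shell:

```bash
driftgaze simulate --seed 1 --out trials.csv
driftgaze fit trials.csv --out fits/
driftgaze smart trials.csv --contrast preview_within_face
driftgaze stats trials.csv
driftgaze run --config config.yaml --out run/
```

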