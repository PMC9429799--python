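# Methods

This note documents the models, numerics and design choices of
`driftgaze` at the level a maintainer or reviewer needs: what is
computed, which knobs matter, what the synthetic data do and do not
emulate, and where the genuinely open decisions were made.

## 1. Diffusion first-passage machinery (`wiener.py`)

**Model.** A Wiener process with unit diffusion constant starts at
`z = zr * a` between absorbing boundaries 0 (noise-patch choice) and `a`
(face choice) and drifts at rate `v`. Per trial, drift is drawn from
`N(v, sv)`, the relative start from `U(zr ± sz/2)` and the non-decision
time from `U(t0 ± st0/2)`; observed RT = first-passage time +
non-decision time. Time is in seconds internally; file formats carry
milliseconds, converted exactly once at the fitting boundary.

**Densities.** The defective lower-boundary density factorises into a
drift-dependent exponential times the zero-drift standardized density
`f0(t/a², w)`, which has a small-time (image/reflection) and a large-time
(spectral sine) series. We switch per evaluation point by the standard
term-count criterion at a truncation target of 1e-7 and verify the two
representations against each other at a much tighter tolerance in the
test suite. The upper boundary is the mirrored process (`v -> -v`,
`w -> 1 - w`).

**Variability marginalisation.** Drift enters only through
`exp(-v a w - v² t / 2)`, so the normal drift mixture has a closed form
and `sv` is integrated exactly (no quadrature). Starting point and
non-decision time use Gauss–Legendre rules (7 nodes each by default; the
doubled-node agreement is a test). A `numba` kernel accelerates the
series loop; the pure-numpy path is mathematically identical and used
when numba is absent.

**Signed CDF.** The fitting stage works on the signed response variable
(`+RT` face, `-RT` noise), whose CDF rises from 0 to 1 with the
lower-boundary probability as its value just below zero. Defective
decision-time CDFs are tabulated by cumulative trapezoid on a
quadratically spaced grid (dense near zero; 384 points by default, 128–
256 during optimisation), renormalised by the computed total mass
(within ~1e-5 of 1), and evaluated by linear interpolation with the
non-decision mixture applied at lookup.

**Simulation.** Euler–Maruyama with a 0.5 ms step plus a Brownian-bridge
crossing probability per step (the path may graze a boundary inside a
step even when both endpoints are interior). The bridge correction
removes the leading discretisation bias: the empirical signed CDF of 1e5
simulated trials agrees with the analytic CDF to KS < 0.01 (test), and
halving the step changes the mean RT by < 1%.

## 2. KS fitting and model comparison (`fitting.py`)

**Objective.** Per participant, `Σ_c (n_c / N) · KS_c` over the four
conditions, with the KS distance evaluated on both sides of every
empirical jump. A weighted sum is a transparent, monotone aggregate of
the per-condition distances.

**Parameterisation.** The optimiser works in an unconstrained space: log
for `a`, `t0`, `sv`; logistic for `zr`; `sz` and `st0` as logistic
fractions of their current legal ranges (`2·min(zr, 1-zr)` and
`2·min_c t0_c`, with a 2% safety margin). Legality is thereby guaranteed
by construction at every iterate.

**Optimiser.** Nelder–Mead with an explicit initial simplex (edge 0.25
in transformed units, halved per chained round). Two details matter and
were found necessary: (i) scipy's default simplex perturbs zero-valued
coordinates by 2.5e-4, which freezes `log a = 0` and near-zero drifts —
hence the explicit simplex; (ii) a single simplex run stalls in ~13
dimensions, so each start is polished by a second run from the incumbent
(a fresh simplex un-collapses the search). Defaults: 3 starts (first may
be a warm start from a nested variant), 2 rounds, 50 evaluations per
dimension per round, seeded jitter.

**Start heuristic.** `t0` from the 2% RT quantile, drift from inverting
the choice-probability rule at `a = 1`, conventional values for the
rest.

**Family fitting.** Variants are fitted in order of increasing parameter
count, warm-started from the best nested fit. A repair pass then
(a) refits any richer variant that fits worse than a variant it nests
(impossible at convergence) from the nested solution, and (b) probes each
nested variant with the richer fit projected onto its space (freed
values pooled by averaging) and refits when the probe beats the incumbent.
This enforces approximate nesting monotonicity and removes most
selection noise from stalled fits.

**BIC and weights.** `BIC = -2 log L + k ln n`, with the log-likelihood
evaluated at the KS-fitted parameters (the only self-consistent desk
definition when the fit criterion is KS) and `k = 7 + 3 · |freed|`,
`n` = all 1024 trials. Per-trial densities are floored at 1e-10 before
the log: responses faster than the fitted minimal non-decision time
would otherwise produce `-inf` likelihoods. The floor is deliberately
harsh — leading-edge misfit is genuine evidence against a variant, and
softening the floor (e.g. to a uniform-contaminant density) measurably
erases the non-decision-time signal that distinguishes the variants.
Information weights are `exp(-ΔBIC/2)` normalised over the family; ties
in model selection break toward the smaller `k` and are logged.

**Maximum likelihood.** Exposed as a non-default criterion
(`criterion="ml"`) for robustness comparisons; it returns `+inf` (with
the offending trials logged) when any trial falls outside the predicted
support, which is exactly why it is not the default.

**Outlier trimming.** "Remove 5% of outliers" is implemented as
symmetric per-tail trimming (`floor(fraction/2 · n)` trials per RT tail
per participant x condition), with a removal log.

## 3. SMART time courses (`smart.py`)

Per participant, the binary outcome at each trial's fixation duration is
smoothed with a Gaussian kernel on a 1-ms grid over [100, 750] ms;
"kernel width 48 ms" is read as the SD (the convention of the method's
toolbox; config-exposed). The kernel mass is kept as the participant's
local weight, so the group curve and the paired t statistic weight each
participant by where they actually have data (weights renormalised to
sum to n per time point, frequency-weight variance, df = n - 1
throughout; points where a participant has no mass contribute zero
weight without changing df). Clusters are maximal runs with |t| above
the two-sided alpha = 0.05 pointwise threshold, scored by summed |t|;
the null swaps each participant's condition assignment (curves and
weights together — with the summed weight being condition-symmetric this
reduces to sign flips of the differences), 1000 permutations by default;
`t_crit` is the 95th percentile of permutation maxima and p values are
position percentiles floored at `1/(n_perm + 1)`. Baseline mode compares
one condition against 0.5. Display CIs put half of the paired-difference
CI on each curve. All clusters are reported; the strongest significant
one is the headline.

## 4. Group statistics (`inference.py`)

Every factor is two-level and within-participant, so each ANOVA effect
is computed as the paired t test of the per-participant contrast score;
`F = t²` with df (1, n-1) is exact, verified against a brute-force
sums-of-squares decomposition and against an independent rm-ANOVA
implementation in the tests. Missing condition x outcome cells raise an
explicit error listing the participants; the pipeline applies listwise
deletion and logs it. Wilcoxon signed-rank tests drop zero differences,
use the exact distribution up to 25 nonzero differences and the
continuity-corrected normal approximation beyond; all tests are
two-sided at alpha = 0.05 with no multiplicity correction.

## 5. Synthetic experiments (`synth.py`)

**Design.** Exactly the study's: 2x2 within design, 256
trials/condition (1024 per participant), conditions randomly
interleaved, inspection location (above/below) and face side
(left/right) balanced within condition, 128 stimuli per category with
each serving 8x as selection and 4x as inspection target and never twice
within a trial (clash repair by pool swaps). Infeasible count
combinations raise an error stating the violated divisibility.

**Generating truth.** The winning model class: `v` and `t0` differ
across conditions (group means v = 0.607/0.320/-0.024/0.096, t0 =
208/211/183/192 ms for FP/FO/NP/NO); `a = 1.0`, `zr = 0.5`, `sv = 0.3`,
`sz = 0.1`, `st0 = 80 ms` shared (plausible conventional values; the
underlying study does not report them).

**Between-participant structure.** Each participant's deviation from the
population means follows a random-effects decomposition over the 2x2
design: `offset(I, P) = s + b·I + c·P + d·I·P` with effect codes ±1.
The slope SDs are fixed by the reported group statistics (contrast-score
SD = |effect| / t · √36): for drift b/c/d = 0.65/0.19/0.17 with shared
s = 0.74 completing the reported marginal SD of ≈ 1.0; for non-decision
time 12.2/6.7/7.8 ms with s = 111 ms against a marginal ≈ 112 ms.
Boundary separation gets a shared 0.15 offset (no dispersion reported).
This structure reproduces simultaneously the marginal violin spreads and
the variances of all three within-participant contrasts — independent
per-condition offsets would match the former and contradict the latter
by a factor of ~3. Illegal draws are rejected and resampled; SDs
rejecting more than half the draws raise an error.

**What the generator does not emulate.** Gaze trajectories, saccade
kinematics, display timing, sequential effects, RT contaminants
(anticipations, lapses) and any participant-level misspecification of
the diffusion model itself. Passing recovery tests therefore show that
the estimation machinery is correct and well-calibrated under the
model, not that real data obey the model.

**Reproducibility.** One master seed derives per-participant substreams
(`SeedSequence(seed, spawn_key=(stage, participant))`); a (config, seed)
pair reproduces byte-identical trial files.

## 6. Problem sizes of the replication studies (`experiments.py`)

Chosen as desk-scale defaults on a single CPU:

- parameter recovery: 12 participants x 256 trials/condition, fitting
  the generating `{v, t0}` variant with the stronger option set
  (2 starts, 2 rounds, 50 evals/dim). Group-mean |error| is ~0.13 for
  drift and ~8 ms for non-decision time.
- model-selection recovery: 20 replicate experiments of 6 participants,
  full eight-variant family per participant with the lean option set
  (1 start, 2 rounds, 30 evals/dim, 128-point CDF grid). The lean
  options were validated against the stronger set on the recovery
  metrics before adoption.
- SMART calibration: 500 null simulations (12 participants x 200
  trials, outcomes independent of RT) at 200 permutations for the
  experiment-wise false-positive rate, and 20 injection runs with a 0.3
  step on [400, 600] ms for sensitivity.

## 7. Known limitations

- BIC from KS-fitted parameters inherits the noise of a non-likelihood
  fit; with ~1024 trials the `{v}` / `{t0}` / `{v, t0}` contest is
  decided by ~10–30 log-likelihood units against a 10.4-unit penalty per
  step, so individual participants can favour a neighbouring variant.
  The across-participant mean weight is the stable quantity.
- The KS objective is insensitive to a handful of extreme-tail trials;
  this is by design (robustness) but means the 5%-trimming refit moves
  parameters little on clean data and cannot be used to detect
  contamination.
- The SMART weighted t statistic follows the published method's
  three-step recipe with the weighting conventions stated above; other
  toolbox-internal conventions (e.g. different df handling at sparse
  time points) would shift cluster statistics slightly, which is why
  numerical equality with any particular implementation is not promised.
- No hierarchical estimation: fits are per participant, as in the
  analysis this package reimplements.
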