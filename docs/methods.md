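# Methods

This note documents the models implemented in `audlex`, the defaults they
ship with, the design choices made where the procedure admitted more than
one reading, and what the synthetic cohort does and does not emulate.

## Adaptive staircase model

Thresholds for the three auditory tasks are estimated with a transformed
up-down staircase: the track steps one continuum level *harder* after
`n_down = 2` consecutive correct responses and one level *easier* after
every incorrect response (`n_up = 1`).  The rule's asymptotic convergence
point is the stimulus level where P(correct) = (1/2)^(1/n_down), i.e.
70.7% for the 1-up/2-down rule.  Tracks stop after 10 reversals; the
threshold is the arithmetic mean of the levels at the last 4 reversals;
each task is run twice and the better (smaller) threshold kept, treating
the estimate as a measure of best sensory capability rather than average
performance.

Stimulus continua are discrete level lists, easiest first:

- **FM depth**: geometric, 100 Hz divided by 1.2 per step down to the 11 Hz
  region, then arithmetic 1 Hz steps.  The geometric schedule never lands
  exactly on 11 Hz; the implementation ends the geometric region at the
  last value above 11 Hz (≈11.22) and runs 11, 10, …, 1 Hz below it.  The
  1 Hz floor is the smallest positive level the printed schedule admits.
- **Rise time**: 41 log-spaced rise times from 15 to 500 ms; the continuum
  levels are differences from the 15 ms reference, so there are 40 levels
  with 485 ms easiest.
- **Intensity**: 40 linear increments of 0.25 dB above the 70 dB SPL
  reference, 10 dB easiest.

Choices the procedure leaves open, resolved as follows: tracks start at the
easiest level (standard practice; guarantees supra-threshold early trials);
steps are always one continuum index (the continua are defined as discrete
lists and no step-halving is specified); the consecutive-correct counter
resets on any error and after every step; direction changes forced at a
continuum boundary count as reversals; a 1,000-trial safety cap marks a
track as not normally terminated.

### Virtual observer

Simulated trials use P(correct | level) = γ + (1 − γ − λ)·F(level), with
γ the forced-choice guess rate (1/3 for the three-alternative odd-one-out
design), λ a lapse rate (default 0), and F a logistic in log stimulus level
with F(threshold) = 1/2 and steepness `slope` (default 4, a moderately
steep psychometric function; at that slope the 70.7% point lies ≈6% above
the threshold parameter in level terms).  Level 0 (no difference from the
reference) yields exactly the guess rate.

### Measuring the convergence point

The clinical 10-reversal stop rule *targets* the 70.7% level but a single
short track does not measure the asymptote.  `convergence_probability`
therefore extends the rule to 60 reversals per track, takes each track's
converged level as the mean of its last 40 reversal levels, and evaluates
the observer's psychometric function at the mean converged level across
tracks (500 tracks in the acceptance script, on a 100-level geometric
continuum spanning 1–100 with the observer threshold interior).  Residual
upward bias from the discrete step size is a fraction of a percentage
point at this granularity.

## Speech-in-noise estimators

**Words (fixed SNR).**  Percent phonemes correct (30 phonemes per 10-word
list) at −5, −10 and −13 dB SNR is fitted by least squares with a
two-parameter logistic in SNR with asymptotes fixed at 0 and 1 — phoneme
scoring has no meaningful chance floor — and the SRT is the fitted 50%
midpoint (the conventional SRT criterion; the procedure names the function
but not the criterion).  Slope sign and asymptote handling are reported in
the fit diagnostics rather than constrained.  Degenerate data (all lists
identical, e.g. all 0% or all 100%) raise a convergence error naming the
problem.  Subject-level simulation operates at the outcome level: phonemes
correct per list are binomial draws with the logistic success probability
(default generating slope 0.35/dB, which spans roughly 33–89% correct
across the three SNRs for a typical −11 dB midpoint).

**Sentences (adaptive).**  A 1-down/1-up track on whole-sentence
correctness — the canonical rule for this task, targeting 50%
intelligibility; the procedure specifies the 2 dB step but not the rule —
starting at a 58 dB presentation level against the fixed 70 dB masker
(first SNR −12 dB).  The threshold is the mean of the last 6 presented
SNRs.  Two 20-sentence lists are simulated as one continuous 40-sentence
track (the level carries over between lists).  Practice lists are excluded
from fitting and averaging in both tasks.  Only SNR matters: shifting
speech and masker levels together leaves the track invariant (tested).

Thresholds and SRTs (lower = better) are inverted by ×(−1) before entering
the z-score pipeline, so every analyzed score is higher-is-better and the
expected correlation matrix is positively oriented.

## Two-step deviance classification

For each measure: (1) z-scores for everyone against the mean and SD of the
full control (NR) sample; (2) controls with step-1 z < −1.65 are removed
— independently per measure — and final z-scores for *all* subjects are
computed against the retained controls' mean and SD.  The trimming step
prevents an inattentive control from inflating the reference SD.  Deviance
is final z strictly below −1.65 (z = −1.65 exactly is not deviant, and the
same strict cut is used for the step-1 exclusion).  Composites (Literacy =
reading+spelling, RAN = colour+object naming, VSTM = digit span+non-word
recall, PA = spoonerisms alone) are unweighted means of member final
z-scores, computed before flagging.  Zero control spread at either step
raises an error naming the measure.

Group prevalence differences use the Pearson chi-square on the 2×2
deviant-by-group table, df 1, **without** continuity correction — this
choice reproduces 8 of the 9 published statistics exactly from their
printed counts; the PA row does not reproduce from its printed counts
under any standard 2×2 statistic (50.93 vs the printed 50.184) and is
treated as a printing erratum, excluded from exact checks.

**Overlap partition.**  Dyslexic subjects are partitioned into PA-only /
RT-only / both / neither deficit cells.  The ID-controlled variant first
excludes ID-deviant subjects entirely and partitions the remainder, with
percentages reported over both the full case group and the ID-clean
subset; the published "30% when controlled" arithmetic is only consistent
with percentages over the clean subset, so in that variant the four cells
sum to the clean-subset size rather than the full case count.

## Group statistics

Transforms: `sqrt`, `reflect_then_sqrt`, `reflect_then_log`, with the
reflection constant = sample max + 1 (stored for invertibility; reflection
reverses subject order, so reflected-transformed scores are
higher-is-better).  Default assignment: sqrt for spoonerism, non-word
recall and rise time; reflect-then-log for FM; reflect-then-sqrt for
intensity.

Both pooled and Welch t-tests are implemented and reported side by side:
the published t-values match pooled arithmetic while the fractional
degrees of freedom suggest a Welch correction, and rather than guess, the
reports print both.  t from raw data equals t from that data's summary
statistics to machine precision.  Bonferroni adjustment is min(1, p·m)
with the per-question comparison count m a required input (the families
are not enumerated in the source procedure).

ANCOVA of the group effect compares the covariates-only model against
covariates+group; partial η² = SS_effect/(SS_effect + SS_error).  Partial
correlations controlling for group residualize both variables on the
binary indicator (t-test p on n−3 df).  "Stepwise" regression is treated
as fixed-order hierarchical entry (PA first, then RT) with all variables
z-scored on the listwise-complete sample, so betas are standardized and
R² change per step is the increment over the previous step; covariate
sets {}, {ID}, {ID, age, IQ} and {ID, age, IQ, group} mirror the reported
models.

## Synthetic cohort

The generator draws, per subject, a vector of latent abilities (literacy,
phonological awareness, verbal short-term memory, rapid naming, slow-rate
auditory, intensity, speech-in-noise) from a multivariate Gaussian with a
fixed correlation matrix, maps each measure to its factor with a loading
√(1−u) plus unique variance u, optionally replaces the latent with a
downshifted "deficit" component (probability p, shift δ, width ω),
re-standardizes the mixture to exact zero mean and unit variance, and maps
to the raw scale affinely with the configured group mean and SD (negated
first for lower-is-better thresholds), finally clipping to physically
valid ranges.  Because the mixture is standardized before the affine map,
group sample moments converge to the configured values regardless of the
mixture, while the mixture controls the mass below a control-referenced
deviance cut.  Deficit draws are shared across a factor's member measures
(one Bernoulli per subject per key), so composites inherit the deficit;
the auditory and speech measures use measure-level mixture keys because
their prevalences differ within a factor.

**Calibration.**  `tune_deficit_mix` grid-searches (p, δ, ω) per measure
or factor — controls first, since they define the reference, then cases
given that reference — simulating the full two-step pipeline on common
random numbers.  Candidates whose clipped raw moments drift more than
0.03 SD from the configured group moments are rejected, and among
near-optimal candidates the most parsimonious mixture (smallest p, then
smallest δ) is preferred jointly across the two groups, so extreme but
equivalent solutions cannot distort the tails or the means.  The shipped
default spec freezes the calibrated mixture together with the deviance
prevalences it implies (estimated at n = 200,000 per group); those implied
rates are the generator's configured operating point, and all lie within
0.007 of the published prevalences.  Two published values deserve note:
a 0% control literacy prevalence is only approachable (the two-step
trimming itself re-inflates any unit-variance reference to a nonzero
deviance floor; the calibrated value is 0.04%), and the most extreme case
prevalences require strongly bimodal case distributions given the
published group moments.

**Recovery testing.**  The acceptance suite generates a cohort at 10× the
study group sizes (540/360) and checks every configured prevalence against
its binomial band.  Eighteen proportions are checked simultaneously, so
the per-comparison level is Šidák-adjusted to give joint 95% coverage —
with eighteen independent 95% bands a perfectly calibrated generator would
still be expected to miss one.  The band treats the deviance flags as
binomial; re-estimation of the control reference from the finite control
sample adds a small extra variance component that the simultaneous
adjustment absorbs in practice.

**What the generator does not emulate.**  Latent abilities are Gaussian
(mixtures of Gaussians under deficit); real score distributions may be
skewed, floor/ceiling-limited, or discrete (digit span, non-word recall
are integer counts in reality, continuous here).  The within-group latent
correlation matrix is implementer-chosen — published correlations pool
over groups, so within-group values were set to plausible magnitudes that
reproduce the qualitative pattern (strong literacy–PA coupling, moderate
phonological inter-correlations, weak auditory–phonology links, a
measurable FM–ID association).  Compensation mechanisms, item content,
test–retest structure and rater effects are not modeled.  Passing recovery
tests therefore shows the *pipeline* is correct and the generator matches
its configured operating point — not that real cohorts obey this
generative model.

## Numerical choices

- Staircase determinism: every stochastic component takes a
  `numpy.random.Generator`; identical (spec, seed) reproduce byte-identical
  cohorts and identical tracks.
- The logistic SRT fit uses Levenberg–Marquardt from a midpoint
  initialized by linear interpolation to 50% and slope 0.5/dB; the fit is
  validated against a dense grid-search oracle to 0.05 dB.
- The latent correlation Cholesky adds 1e-12 to the diagonal to tolerate
  semi-definite matrices.
- Chi-square tail probabilities, t/F tails come from `scipy.stats`;
  OLS/ANCOVA fits from `statsmodels`.
- Waveforms: the speech-weighting filter is a parametric long-term-average
  speech-spectrum style tilt (flat to 500 Hz, −10 dB/decade in power
  above), a documented synthetic stand-in for unspecified original
  hardware filtering; absolute SPL is not realizable digitally, so levels
  are relative to a configurable digital reference.

## Known limitations

- The deviance pipeline assumes measures are pre-oriented higher-is-better;
  `oriented_scores` handles this for generated cohorts, but user-supplied
  tables must follow the same convention described in the spec file.
- The staircase engine models stationary observers; attention lapses are a
  constant rate, not time-varying.
- Simulated sentence tracks treat sentences as exchangeable Bernoulli
  trials; list-equivalence and sentence-difficulty structure are not
  modeled.
- Bonferroni families must be supplied by the analyst; the package does not
  guess how many comparisons belong to a "question".
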