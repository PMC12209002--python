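# Methods

This note documents the models, parameter choices and numerical decisions
behind `capdyn`, in the order the pipeline runs them.

## Synthetic cohort model

The generator is a hidden Markov emission model chosen to mirror the study
design the pipeline targets: 22 subjects, two imaging sessions
(pre-surgery and 3-month follow-up), behavioral testing at three
timepoints (pre, 1 week, 3 months; the 1-week timepoint has behavior
only, as fMRI is acquired at pre and 3 months).

**States and emission.** A chain over K = 4 co-activation states plus a
noise-only baseline state 0. State maps are unit-variance random patterns
over P = 90 parcels; all states load positively (≈ +1.5 z) on a 9-parcel
seed region, so seed-driven frame selection can capture all of them. A
CAP frame emits `a·map + ε` with amplitude `a ~ N(1, 0.25²)` and i.i.d.
parcel noise `ε ~ N(0, 0.8²)`; baseline frames are pure noise. At this
SNR a single frame correlates ≈ 0.75 with its own map — high enough for
frame-level clustering to work, low enough that recovery is not trivial.
No HRF convolution is applied by default (CAP analysis treats frames as
instantaneous samples; an optional convolution would only blur state
boundaries), and T = 180 frames at TR = 2 s keeps runs desk-scale. These
dimensions are package defaults, not estimates of any particular
acquisition, and are all configurable.

**Transition structure.** Baseline persists with p = 0.60 and enters each
CAP with p = 0.10; CAP states persist with p = 0.55 (the planted
resilience), return to baseline with p = 0.36 and switch directly between
CAPs with p = 0.03 per target. Routing most switches through the baseline
hub keeps the empirical transition graph sparse at T = 180, which is what
makes betweenness vary across subjects; a chain with dense direct CAP-CAP
switching makes every direct edge a shortest path and betweenness
degenerates to a constant.

**Group effect.** Half the subjects form a deficit group whose FPN-like
state (state K) has its self-transition scaled by 0.62 and its incoming
transitions scaled by 1.7 (rows renormalized): a less stable, more
switched-through executive state. These scales were fixed once, by Monte
Carlo, so that the package's prescribed recovery checks have comfortable
power at n = 22 (deficit model power 0.94; measured type-I error 0.054 at
nominal 0.05 when the scales are set to identity).

**Behavior.** The planted latent axis is the standardized sum of the FPN
state's occurrence and resilience, computed per session from each
subject's *realized* metrics. Scores are generated on the adjusted
clinical scale (TMT-A/B in seconds, higher = worse; attentional matrices
count, higher = better) as `intercept + scale·(loading·latent + noise)`,
with TMT B−A derived exactly as TMTB − TMTA at every timepoint. The pre
and 3-month scores use their session's latent — so the 3-month − pre
score change covaries with the change in FPN dynamics (the axis the PLSC
must find) while group means regress to the pre-surgical baseline — and
1-week scores of the deficit group are additionally shifted past their
cutoffs (TMT-A +70 s, TMT-B +90 s, matrices −8), which is what the
deficit classifier is supposed to detect. Cutoffs (94 s, 283 s, 187 s,
31) are typical adjusted-score thresholds for these tests.

**Determinism.** One cohort seed governs everything; per-(subject,
session) streams are derived by SHA-256 hashing of (seed, subject,
session), so adding subjects or sessions never perturbs existing ones.

What the generator does *not* emulate: hemodynamic autocorrelation,
physiological/vascular noise, motion and scrubbing structure, lesion
effects on signal, and spatial smoothness within networks. Passing
recovery tests therefore demonstrates correctness of the machinery under
a clean state-emission model, not performance on real patient data.

## CAP extraction

- Per-run z-scoring uses the population SD over usable frames; censored
  frames pass through untouched and are never selected or counted.
- Frame selection keeps the top 15% of seed z-scores per run (the common
  convention in the seed-based CAP literature; the threshold, a z-cut
  mode, and a polarity mode that adds sign-flipped deactivation frames
  are all configurable). Selected frames are pooled across all subjects
  and both sessions so that pre and post share one state space — without
  this, longitudinal deltas would compare incommensurable labels.
- k-means uses distance 1 − Pearson r. Frames and centroids are centered
  and unit-normalized, making the update a spherical k-means whose
  objective is provably non-increasing; this is asserted at every
  iteration. Greedy k-means++ seeding, 20 restarts for the final fit,
  deterministic given the seed. Emptied clusters are re-seeded at the
  worst-fit frame (deterministically) rather than failing, which also
  handles degenerate all-identical inputs. CAPs are renumbered by
  descending member count; correlation ties in assignment go to the lower
  CAP index.
- Consensus model-order selection runs **one** k-means fit per resampled
  80% subset (100 resamples, shared across candidate k). This is
  deliberate: the instability of a single fit across subsamples and
  initializations is exactly the signal PAC measures. Pooling many
  restarts per resample makes the merge pattern at k below the true
  order deterministic, driving PAC(k) to 0 for every k ≤ K_true, after
  which the argmin-with-smaller-k tie-break can never select the true
  order. PAC uses the (0.1, 0.9) window; ties select the smaller k.
- On pipeline runs the recovered CAP corresponding to the designated
  FPN-like state is identified by Hungarian matching of recovered maps to
  the planted maps (available because simulation retains ground truth);
  on real data this identification is the analyst's map-inspection step.

## Temporal metrics

Definitions are in the README. Numerical choices:

- The baseline state participates in transitions and in all
  normalizations (it is a real dwell state); reporting layers keep CAP
  states 1..K.
- Transitions across censored gaps are skipped; dwells are truncated at
  gaps; metrics are invariant to appending censored frames (tested).
- IN-/OUT-degree are normalized by the total number of between-state
  switches, making them comparable across subjects with different
  switch rates. Note that a state's entries and exits differ by at most
  one, so IN- and OUT-degree are collinear within any one sequence;
  models therefore never carry both (see below).
- Betweenness: edge length −log p with p the off-diagonal row-normalized
  transition probability (higher-probability routes are shorter, and
  lengths add along paths, unlike 1/p). Lengths are floored at 1e-6 so
  probability-1 edges cannot create zero-length cycles. Path counting
  uses Brandes-style accumulation over a shortest-path DAG built with a
  1e-9 tie tolerance, and each node's value is normalized by the number
  of ordered source–target pairs that actually have a path, so a chain's
  middle node scores exactly 1 and values stay in [0, 1] on graphs that
  are not strongly connected. Unvisited states score 0; graphs with
  fewer than three active nodes score 0 everywhere.
- Resilience of a never-left state is its self-transition probability;
  for a never-visited state it is reported as 0 with an explicit
  `resilience_defined = False` flag.

## Deficit classification and score deltas

A subject has a deficit at a timepoint (default: 1 week) if ANY score
lies strictly on the impaired side of its cutoff after orientation
normalization — above the cutoff for timed scores, below for accuracy
scores; a score exactly at the cutoff is not impaired. Classification is
invariant to jointly rescaling a score and its cutoff (tested as a
property). Score deltas are value(3m) − value(pre).

## Grouped behavioral PLSC

Brain and behavior blocks are z-scored within group (ddof 1), per-group
cross-correlation matrices `Yg'Xg/(n_g−1)` are stacked to R, and R is
decomposed by SVD. Correlations rather than covariances because the
behavioral scores live on heterogeneous scales; within-group
standardization removes absolute group differences by construction (an
invariance test adds an affine shift to one group and checks that nothing
changes). Sign convention: the largest-magnitude element of each brain
salience is made positive.

Permutations shuffle behavior rows within group (the exchangeability unit
of the grouped analysis) and compare sorted singular values with the
add-one estimator, so p ≥ 1/(n_perm+1). **Procrustes alignment of the
permuted solutions is available but off by default**: aligning permuted
saliences to the observed ones systematically shrinks the permuted
singular values, and under a true null the aligned test rejects ≈ 42% of
the time at nominal 5% (measured over 200 replicate null cohorts). The
raw sorted-singular-value comparison measures 4–6%. The bootstrap
(within-group resampling, 5th–95th percentile salience intervals, robust
⇔ interval excludes 0) does use Procrustes alignment, where it is the
correct tool for sign/rotation indeterminacy rather than an inferential
shortcut. No multiple-testing correction across components is applied by
default; a Bonferroni flag exists.

## Outcome models

Predictors are standardized before fitting. Because IN- and OUT-degree
are collinear by flow conservation, each transition model carries one of
them: Model 2 (deficit ~ presurgical OUT-degree, logistic), Model 3
(deficit ~ occurrence + resilience, logistic), Model 4 (1-week TMT-A ~
IN-degree), Model 5 (1-week TMT-B ~ OUT-degree), and the Model 1 mixed
model uses IN-degree only. Model 1 regresses the longitudinal score on
deficit status, timepoint, the FPN state's metrics (session-matched: pre
metrics describe the pre and 1-week rows, post metrics the 3-month rows)
and deficit × time interactions, with a subject random intercept.
Constant predictors (possible for betweenness in unusually regular
cohorts) are dropped from Model 1 with a warning.

**Logistic inference.** Coefficients come from IRLS; complete or
quasi-complete separation is detected and flagged rather than silently
diverging. Reported statistics are Wald z, but p-values are drop-one Rao
score tests: at n = 22 the Wald test loses power exactly when effects are
strong (Hauck–Donner) and the likelihood-ratio chi-square is measurably
anticonservative (empirical type-I 0.076 at nominal 0.05), while the
score test measures 0.053 with power 0.94 against the shipped group
effect.

**Mixed model.** Gaussian random intercept fitted by REML: the variance
ratio λ = σ²_subject/σ²_residual is profiled by bounded one-dimensional
minimization of the restricted likelihood on [0, 1e4] (exact λ = 0 is
compared explicitly so the OLS boundary case is exact), then fixed
effects come from GLS at λ̂. Per-subject blocks use the closed Woodbury
form, so no matrix larger than p × p is ever factored. Wald t with
residual degrees of freedom is a documented approximation (no
Satterthwaite); at the package's scale the difference is negligible, and
the implementation is verified against closed-form balanced one-way ANOVA
estimators and against an independent REML implementation in the test
suite. Random slopes are deliberately out of scope: two or three
observations per subject cannot support them.

## Problem sizes and reproducibility

Default experiment sizes — 22 × 2 × 180 × 90 cohorts, 100 consensus
resamples over k = 2..8, 1000 permutations, 500 bootstraps, and 200-
replicate calibration studies — were chosen so that any single analysis
or check completes in seconds to a few minutes on one CPU. All
randomness flows from explicit seeds; pipeline runs write a provenance
manifest (config hash, package version, seed, SHA-256 per artifact) and
rerunning an identical configuration is bit-identical.

## Known limitations

- The generator's clean emission model overstates how well CAP extraction
  will work on real BOLD data (no autocorrelation, motion or lesion
  effects); recovered-metric analyses are correspondingly attenuated
  relative to planted-metric analyses even here.
- Betweenness on 5-node empirical graphs is a coarse, heavily tied
  statistic; its variance across subjects depends strongly on graph
  sparsity (hence on scan length and switching rates).
- Wald-with-residual-df inference in the mixed model and the
  add-one permutation p floor are small-sample approximations.
- The DAN seed path is exercised with the same machinery as the FPN path
  but the shipped generator plants only one seed system.
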