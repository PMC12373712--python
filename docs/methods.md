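# Methods

## Scope and model

`slmvpa` implements a trial-wise searchlight decoding chain for an
occluded-motion (interception) fMRI paradigm, exercised entirely on
synthetic data with planted ground truth. The chain is: event design →
volumetric BOLD simulation → condition / single-trial GLM → ROI-restricted
searchlight LDA → selection-plus-permutation group inference → trial-history
contrasts. Every stage is deterministic given one integer seed; each
stochastic operation draws from a named substream
(`slmvpa._rng.substream`), so changing the number of draws in one stage
never perturbs another.

## Experiment designs

A session is four runs of an interception task: a dot travels horizontally
(fast 0.250 s or slow 0.450 s for the 200 px segment, i.e. 800 px/s vs
~445 px/s), then turns up or down. Within a run the horizontal velocity
predicts the vertical direction (configurations up-fast/down-slow or
up-slow/down-fast, two runs each). Congruent vertical segments last
0.400 s (fast) or 0.716 s (slow); incongruent trials change speed at the
turn and their vertical segment is held at the constant 0.716 s regardless
of horizontal speed. Defaults are the paradigm's printed counts — 30
(visible) or 50 (occluded) trials per direction x velocity cell per run,
i.e. 240 / 400 trials per session, with 30% incongruent trials in the LP
context (72 and 120, exactly counterbalanced: 18 and 30 per cell).

The inter-trial interval is read as an integer draw from a Poisson law
with rate 4 s, rejected and redrawn unless it falls in {2..6} s. This is
the simplest law matching the stated name and support; the rate itself is
a package choice (the truncated distribution is insensitive to moderate
rate changes). Run length is `ceil((last offset + 20 s) / TR)` — room for
HRF decay; first onset at 10 s.

Reduced designs (`trials_per_cell_per_run` below the defaults) keep the
full run structure, counterbalancing, and the 30% incongruency fraction
(rounded per cell); they exist so that multi-subject Monte-Carlo studies
fit in minutes rather than days, and all desk-scale results below use them.

## BOLD simulation

Grid: isotropic voxels (default 2.2 mm), TR 2 s. Three pairwise-disjoint
compact blobs stand in for retinotopically delineated lower V1, upper V1
and V5 (each the `region_size` ≥ 150 voxels nearest a jittered center,
restricted to that center's nearest-center cell). A contiguous cap of each
V1 blob (default 10%) is tagged "reappearance-responsive" and excluded from
all pattern analyses downstream.

Signal per mask voxel: a per-condition spatial pattern (one z-scored
Gaussian pattern per direction x velocity cell, plus an additive
incongruency pattern), scaled by a trial amplitude and convolved with the
canonical HRF — a difference of gamma densities (response peaking ~5 s,
undershoot at ~15 s, ratio 1/6, 32 s support), built at 0.1 s microtime,
unit peak, sampled at volume times. A uniform `mean_response` component,
shared by all mask voxels, carries the univariate activation on which
trial-history modulation rides (the z-scored patterns are spatially
zero-mean by construction, so without it an ROI-mean analysis would see
nothing). Visible and occluded patterns of the same condition are
constructed with correlation ρ (default 0.7): occluded = ρ·visible +
√(1−ρ²)·independent. Category-switch trials (CI / IC) have their amplitude
multiplied by `1 + switch_increment`; optional multiplicative trial
amplitude jitter makes single-trial recovery measurable.

Noise: AR(1) (default coefficient 0.4, innovation SD 1.0 — the single-trial
CNR is therefore `amplitude` in these units), a cosine drift of period
128 s with random per-voxel phase (amplitude 1.0), and six motion
parameters as Gaussian random walks (step SD 0.01) that carry no signal.
What the simulation does **not** emulate: spatial noise correlations,
physiological noise, motion-correlated signal, susceptibility artifacts,
inter-subject anatomical variability. Passing tests therefore show the
*analysis chain* is correct and calibrated under these assumptions, not
that real data would behave as cleanly.

## GLM estimation

Condition GLM: per run, each condition's onsets (impulses at the initial
trajectory onset; sub-second durations are negligible against the HRF) are
convolved with the canonical HRF and its temporal (1 s onset-shift
difference) and dispersion (numerical ∂/∂dispersion) derivatives; six
motion regressors, a DCT drift basis (128 s cutoff) and an intercept
complete the model. OLS per voxel; only canonical-HRF coefficients are
kept, averaged over the runs containing the condition. No prewhitening:
OLS keeps the noiseless oracles exact, and noise autocorrelation is a
simulation parameter, so the calibration properties remain meaningful.

LSS: per trial, the model holds that trial's regressor, one pooled
regressor for all other trials (their summed convolved onsets — the most
common single-pooled-regressor variant), and the nuisance set. The
trial-of-interest coefficient is retained. Trials whose HRF support is
truncated by more than half (onset within 16 s of run end) are dropped
with a logged count; single-trial runs fall back to a plain GLM with a
warning.

## Searchlight decoding

Spheres of radius 4.4 mm around every retained ROI voxel (33 voxels at
2.2 mm for interior centers, verified against exhaustive lattice
enumeration), intersected with the retained voxel set. Partitions:
trials are stratified by class into 4 folds; each training split is
balanced by randomly subsampling the majority class; the whole partitioning
is repeated 4 times (16 splits). Stratification is by class only — the
scheme leaves out trials, not runs — with runs recorded for permutation
use.

The classifier is binary LDA with the pooled within-class covariance
shrunk toward a scaled identity by the analytic Ledoit-Wolf coefficient;
ties (discriminant exactly 0) break toward the first class in sorted label
order. Three numerically equivalent implementations exist and are tested
against each other: a batched explicit-covariance route, a dual (Gram
space / Woodbury) route in which every shrinkage statistic derives from
the n x n Gram matrix, and a compiled (numba) scalar kernel of the dual
route in float32 used in the permutation hot loop. The dual route matters
because training sets (≈ 12–45 trials) are smaller than the 33-voxel
sphere dimension, cutting the per-problem solve from O(f³) to O(n³).
Padded sphere slots point at an all-zero dummy column whose discriminant
weight is exactly zero.

Cross-phase decoding trains on all balanced visible trials and tests on
balanced occluded trials; since the sets are disjoint phases, the four
repetitions are balancing redraws rather than folds.

## Selection and permutation inference

Per subject and analysis, spheres at or below 0.5 are discarded and the
top 5% of survivors retained (round-half-up, floor one sphere; boundary
ties break by ascending center index); the subject statistic is the mean
accuracy over the selected spheres. When no sphere clears the cutoff the
statistic falls back to the single best sphere — keeping every subject in
the group average is required for calibration (conditioning on subjects
with "lucky" maps was measurably anticonservative).

The subject null shuffles class labels within each run (preserving per-run
class counts), regenerates the balanced partitions, and recomputes the
**identical** statistic — cutoff, top-5% selection, mean — on every
permuted accuracy map. This reselection is a deliberate design choice:
the selected-sphere mean is inflated above 0.5 even on pure noise, and
only a null that carries the same inflation cancels it. A fixed-center
variant (permuted accuracies averaged at the originally selected centers
only) is available as `reselect=False` for comparison; it centers on
chance and rejects essentially always on noise — it is not valid for
inference and the tests demonstrate both behaviours.

Group inference averages subject nulls per iteration; with the true group
mean this yields N + 1 group values and
`p = #(permuted ≥ true)/(N + 1)`, which can be exactly zero; the
conservative `(b + 1)/(N + 1)` is reported alongside, clearly labelled,
never substituted. Sphere-center overlap across analyses is counted
pairwise and all-ways per subject, with a closed-form hypergeometric
reference in the tests. A paired-t utility compares per-subject accuracy
pairs (e.g. HP vs LP); both inputs carry the same selection bias, which is
documented rather than corrected.

## Trial history

Each trial after the first of a run is labelled by the ordered congruency
pair it completes: the first letter is the *previous* trial's category,
the second the current one, so CI is an incongruent trial preceded by a
congruent one. (The source literature is internally inconsistent between
this pair-order reading and an "after" reading in a figure caption; the
pair-order reading of the running text is implemented, and this flag is
surfaced here rather than silently resolved.) Category means per subject
enter a one-way repeated-measures ANOVA (statsmodels `AnovaRM`; F on
(3, 3(n−1)) df, no sphericity correction — a documented limitation) plus
six paired-t contrasts with Bonferroni correction (p x 6, capped at 1).
Degenerate inputs (identical category profiles) define F = 0.

## Known limitations and quantified biases

Two properties of the trial-wise chain deserve emphasis; both are
measured by the test suite.

**Below-chance bias of leave-trials-out CV on LSS betas.** Single-trial
betas of same-run trials are positively correlated (~r = 0.13 in this
configuration even under pure white measurement noise) through the shared
nuisance and pooled-trial projections. Excluding a test trial from
training removes its positively correlated same-class contribution
asymmetrically, depressing accuracy below 0.5 — about 0.45 at 16 trials
and 0.48 at 64 trials per subject, shrinking roughly as 1/n. Run-wise
mean-centering overcorrects at these trial counts (the few-samples
centering artifact) and is not applied. The searchlight/classifier stage
itself is exactly calibrated on independent trial patterns; the bias
enters upstream and is inherent to trial-wise designs that partition
correlated trials.

**Approximate exchangeability of the label permutation.** Trial durations
differ by condition (0.65 s vs 1.17 s), so the onset grid is weakly coupled
to the true label sequence; shuffling labels over fixed onsets is therefore
only approximately exchangeable. Together with the above, the group
permutation test shows a mildly elevated false-positive rate at the
smallest problem sizes (≈11% at a nominal 5% with 16-trial subjects),
within the 3-sigma binomial band asserted by the tests.

## Problem sizes used in the tests

Monte-Carlo tests use reduced designs chosen once: null-calibration runs
use 4 subjects x 16 trials (12³ grid, 150-voxel regions, 99 permutations,
100 repetitions); cross-phase recovery uses 6 subjects x 40 + 40 trials at
CNR 1.0 and ρ = 0.7; trial-history recovery uses 16 subjects x 40-trial LP
sessions with a 0.5 switch increment; type-I calibration of the inference
module uses 8 subjects x 100 repetitions on direct 24-trial pattern
matrices. Oracles: HRF regressors vs direct microtime summation (≤1e−6
relative), noiseless GLM/LSS recovery (≤1e−4), sphere membership vs
lattice enumeration (exact), RM-ANOVA F vs a sums-of-squares
decomposition (≤1e−10), and the dual/batched/compiled LDA routes against
scikit-learn's shrinkage LDA.
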