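# Methods

`lrspectrum` implements a voxelwise "learning-rate spectrum" analysis for
model-based fMRI, together with a synthetic-data test bed that gives every
analysis a known ground truth. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic results do and do
not establish about real data.

## Task and behavioral model

The task is a probabilistic reversal-learning game: two options carry
visible reward magnitudes and hidden reward probabilities. A session has a
*stable* sub-session (60 trials, one option rewarded on 75% of trials, the
other on 25%) and a *volatile* sub-session (80/20, the better option
swapping every 20 trials); outcomes are coupled, so exactly one option is
the rewarded one on each trial. The order of sub-sessions is
counterbalanced across subjects. The volatile sub-session defaults to 60
trials so the two halves are comparable in length.

Subjects are replaced by softmax Rescorla–Wagner agents: each agent keeps a
running estimate q of p(A rewarded) with its own learning rate (drawn
uniformly from 0.15–0.5 across the default 17 agents), values options as
magnitude × probability (magnitudes are independent uniform integers
1–100), and chooses by softmax with inverse temperature drawn from 3–8.
The analyses condition on observed choices and outcomes, so behavior only
needs to be plausible, not human-calibrated.

Event timing mirrors a slow event-related design: stimuli shown for a
jittered 4–8 s plus a lognormal response time (median 1 s, sigma 0.3), a
4–8 s anticipation phase, a 3 s outcome phase, and a 3–7 s inter-trial
interval — about 21 s per trial, ~840 volumes at TR 3.0 s.

## Value model

For every learning rate alpha the delta rule

    p(a_i) = p(a_{i-1}) + alpha * (R_i - p(a_{i-1}))

tracks the estimated probability that option A is rewarded, initialized at
p0 = 0.5 (an uninformative prior; the initialization washes out after a few
trials for all but the smallest alphas). Because outcomes are coupled, one
outcome sequence drives the update for both options and p(B) = 1 − p(A)
exactly. The decision-phase signal on trial i is the *pre-outcome* estimate
for the chosen option, p(chosen); the outcome-phase signal is the
probability prediction error PE = R − p(chosen), unweighted by magnitude.
Learning is treated as continuous across the unannounced sub-session
transition: sub-session analyses slice the full-session traces rather than
resetting them, because the split is a property of the measurement, not of
the learner.

## Regressors and design matrix

Every regressor is a continuous-time boxcar (onset, duration, parametric
height, demeaned across trials) convolved with the canonical double-gamma
HRF (peak 6 s, undershoot 16 s, dispersions 1, undershoot ratio 1/6),
sampled at the volume times, and high-pass filtered by projection on a
unit-norm discrete-cosine drift basis with a 100 s cutoff. Convolution is
always done on the full-session time grid and then sliced to a segment, so
responses spilling into a segment from just before its start are kept.
Value and PE regressors are additionally scaled to unit variance so betas
are comparable across learning rates; design-matrix columns are filtered
(hence demeaned) but not variance-scaled.

The base design has the three phase main effects (decision, anticipation,
outcome), four parametric modulators (chosen magnitude and log RT and
stay/switch at decision; chosen magnitude at outcome), the temporal
derivative of each (first-order finite difference of the convolved column),
six smooth nuisance series, and an intercept — 21 columns. A constant
modulator (e.g., an agent that never switches) produces an all-zero column,
which is dropped with a warning. The first trial's stay/switch is coded 0.

## The 30-learning-rate grid

The 99 convolved value regressors (alpha = 0.01…0.99) are nearly collinear
at high alpha, so mapping uses 30 learning rates chosen to be equally
spaced in *neighbor correlation*. Because the regressors form a smooth
one-parameter family, 1 − corr between neighbors shrinks quadratically in
the alpha step; the quantity that accumulates additively along the family
is the correlation chord metric sqrt(2(1 − corr)). We therefore place 30
positions (endpoints included) equally spaced along the cumulative chord
arc length, map each back to the nearest 0.01-grid alpha (ties toward the
lower alpha), average the selections across subjects and all three
(sub-)sessions, and round to two decimals. A cumulative sum of raw
(1 − corr) was tried and discarded: it over-samples low alpha severely and
cannot reproduce the published grid shape; the chord metric reproduces it
to within one grid position. The package ships the canonical published
30-value list as its default mapping grid; `select_lr_grid` recomputes it
from data.

## Voxelwise mapping

Data are prewhitened per voxel: an AR(1) coefficient is estimated from the
lag-1 autocorrelation of base-model OLS residuals (clipped to ±0.97), and
the exact quasi-difference transform (first row scaled by sqrt(1 − phi²))
is applied to the voxel and all design columns; whitened OLS then equals
GLS under an AR(1) covariance, which a dense-matrix oracle test confirms.
Each voxel is fit with 30 GLMs — base design plus one learning rate's value
regressor and its PE regressor — via the Frisch–Waugh–Lovell route (one QR
of the whitened base per voxel, then a 2×2 solve per learning rate). The
best-fitting learning rate is the rank (1–30) of the value regressor with
the highest *signed* beta, the lowest rank on ties; |beta| is available as
a config variant. Note a limitation inherent to this criterion: with the PE
co-regressor present, an immediate neighbor's partial beta can exceed the
true rank's beta by a fraction of a percent even in noiseless data, so the
criterion is accurate to ±1 rank by construction and its precision in noise
is an empirical property (at the default signal strength: Spearman ≈ 0.93
against ground truth, mean error ≈ 2.2 ranks over 500 voxels).

Sub-session splitting assigns to the first segment all volumes up to and
including the volume containing the last outcome onset of the first
sub-session, plus two volumes for the hemodynamic delay; the second segment
is the disjoint remainder. Segment designs and banks are rebuilt on the
segment's volumes (re-filtered and re-demeaned) from the sliced traces.

## Model evidence (is any learning-rate signal present?)

The trial × 99 matrix of p(chosen) traces is column-demeaned and
decomposed by SVD; its first three left singular vectors capture ~99.7% of
the variance in simulation, so three components stand in for the whole
bank. They are turned into regressors like any other modulator
(decision-phase boxcar, HRF, filtering). Per voxel and subject, the base
GLM and base+3-components GLM are scored by Gaussian AIC,
n·ln(RSS/n) + 2(k+1), and −AIC/2 enters random-effects Bayesian model
selection: variational Dirichlet updates (alpha0 = 1, convergence at
max |Δalpha| < 1e-4), exceedance probability by the regularized incomplete
beta function for K = 2 (a 10⁶-sample Dirichlet Monte-Carlo oracle agrees
to < 0.005), the Bayes omnibus risk from the free-energy comparison with
the equal-frequency null, and the protected exceedance probability
PXP = EP·(1 − BOR) + BOR/K. Per-subject log evidences are mean-centered
across models before the updates (only differences are meaningful).

Under the null, the AIC penalty makes the base model consistently — not
equivocally — better, so null-voxel PXP for the learning-rate model sits
near 0 rather than 0.5; the false-flag rate at the 0.95 threshold is
essentially zero in simulation.

## Topography

Per subject, recovered ranks are regressed on voxel (x, y, z) plus an
intercept; a flat or collinear axis is dropped with a warning. The null is
10,000 random permutations of coordinates against ranks (vectorized via a
QR projector), reported as the permuted-mean r² and a one-sided exceedance
p with the +1 correction. Group inference is a paired t-test of true vs
permuted-mean r² across subjects, plus a one-sample t-test of the chosen
axis's slope (rank units per voxel step) against zero. Ranks, not raw
alphas, are the regressand throughout. The permutation test's true type-I
rate measures 4.5–5.3% at nominal 5% over thousands of null simulations.

## Volatility adaptation

Two group tests distinguish the two adaptation mechanisms. The *LR shift*
test takes per-voxel (volatile − stable) rank differences, averages within
subject, and t-tests the subject means against zero (the sign convention is
volatile-minus-stable so "faster under volatility" is positive; a flag
flips it). A Lilliefors normality check on the pooled rank distributions is
reported descriptively. The *coupling* test computes, per subject and
sub-session, the Pearson correlation across voxels between best rank and
best beta, Fisher-z transforms it, and paired-t-tests z_stable − z_volatile
(a gain-type boost of currently-relevant timescales drives this negative).

The generator encodes the mechanisms as regimes: *shift* adds a configured
rank offset (default +5) to every voxel's generative rank in the volatile
segment; *gain* multiplies the value amplitude (default ×2) where the
voxel's rank matches the regime (ranks above 15 in the volatile segment,
15 and below in the stable one). A subtlety matters here: the generative
value signal is standardized *within each segment*, holding the
standardized effect size constant — this is the correct "no gain change"
null. Injecting a constant-amplitude whole-session signal instead leaks a
spurious coupling change (about −0.3 in delta-z, significant at n = 17)
because low-alpha value regressors lose most of their within-segment
variance to the high-pass filter. With the constant-effect-size null, the
2×2 mode-identifiability property holds: shift triggers only the shift
test, gain only the coupling test, combined both, at ~4.3 recovered ranks
(generative +5 attenuated by clipping at rank 30 and estimation noise) and
delta-z ≈ −1.8.

## Connectivity

Each voxel's residual after projecting out the *full* design — base
columns plus all 30 value and all 30 PE regressors, entered once per
segment together with per-segment intercepts — is averaged within its
best-LR bin per region; the 30 bin series of one region are correlated
with the 30 of the other (Fisher z; empty bins are missing, never imputed;
|r| = 1 cells are flagged missing). Diagonal affinity is the per-subject
Pearson correlation between z values and −|i − j| over populated cells,
one-tailed t-tested (> 0) across subjects. The 60+ LR columns are heavily
collinear, so rank-revealing pivoted-QR pruning drops dependent columns
before projection and reports the retained count.

The segment-wise residualization design (rather than whole-session columns
only) exists for the same reason as segment standardization in the
generator: segment-granular learning-rate structure must not masquerade as
residual connectivity. With it, the diagonal-affinity test is calibrated
(≤ 5% rejections under a zero-strength null; 0/40 full-pipeline null groups
significant in a calibration run) and detects the injected component
decisively at the default strength (0.5 sd in signal units), with effect
size monotone in the injected amplitude.

The injected shared component is one latent series per rank, correlated
across neighboring ranks (Gaussian kernel, sd 1.5 ranks, giving the graded
off-diagonal falloff), temporally smoothed, orthogonalized against the full
residualization design (so ≥ 90% of it survives residualization by
construction), and added to matching-rank voxels of both regions.

## Synthetic BOLD generator

A voxel's series is a_value·X_value[rank] + a_pe·X_pe[rank] + nuisance
loadings + AR(1) Gaussian noise (default phi 0.3, sd 1). Amplitudes are
calibrated per voxel so the value regressor explains a target share of the
non-value variance — default 8%, a weak, fMRI-like effect (PE: 2%).
Regions are integer-grid boxes; ranks are clip(round(affine(y) + jitter),
1, 30) with default slope 2.5 ranks/voxel and jitter sd 3. Null-region
voxels carry no value or PE signal.

What the generator does *not* emulate: spatial autocorrelation
(smoothness) of noise, physiological noise structure, scanner drift beyond
what the filter removes, HRF variability across voxels (the derivative
columns exist but the generative HRF is the canonical one), and
registration/anatomy. Passing tests therefore establish that the
*statistical machinery* is correct and calibrated under its stated
assumptions — not that the effects exist in real brains, nor how the tests
behave under spatially-correlated noise, where permutation nulls over
voxels would be optimistic.

## Problem sizes and numerical details

Reference studies use the study-scale defaults: 17 subjects, 120 trials,
~840 volumes; the evidence study uses a 200-voxel signal region and a
100-voxel null region; recovery uses 500 voxels; grid selection uses all
51 subject-session banks. Group simulations in the property tests use
smaller regions (typically 40–160 voxels) chosen for turnaround, with
group size held at the study's n = 17 wherever a significance claim is
made. Tolerances: SVD/GLS/closed-form oracles at 1e-8–1e-12 (exact
algebra); Monte-Carlo assertions at 2–3 standard errors of their
simulation size. Degenerate inputs (constant modulators, rank-deficient
designs, zero-variance bins, |r| = 1 correlations, zero-variance slopes)
are dropped or guarded with warnings rather than propagated as NaN.

All randomness flows from explicit integer seeds; subject s of a run with
master seed m uses m + 1000·s plus small fixed offsets per component, so
every figure and table regenerates bit-identically.
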