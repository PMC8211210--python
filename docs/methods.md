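# Methods

This note documents the models, numerical choices and design decisions
behind `gatepipe`, and what the synthetic-data tests do and do not show
about real recordings.

## Task model

The reference-back-2 task is simulated as a continuous stream: one stimulus
per trial, category drawn uniformly (letter/symbol), token drawn uniformly
within category, frame color drawn with probability `bias_high` (default
0.75) for the phase's frequent color.  Which color is frequent first is
randomized per session, and the bias flips at the session midpoint (hence
`n_blocks` must be even).  The first two trials of each block are forced
updating trials covering both categories and are flagged for exclusion.

Memory replay follows the task rule exactly: the matching decision compares
the stimulus against its own category's slot *as held before the current
trial*, and updating trials then overwrite only that slot.  Switch labels
are computed across block boundaries (the task is continuous; the excluded
block-initial pairs make the choice immaterial for analysis), and are
defined on behavior-independent quantities: input = WM state changed,
output = probed category changed, response = **correct** response changed
(not the emitted choice), so EEG condition labels never depend on the
subject's accuracy.  No constraint is placed on stimulus-identity repeats
at generation; the similarity analysis removes them afterwards instead.

Exclusions: block-initial pairs, omissions, RT < 0.200 s (strict) and
RT > 3 s.  Rows are flagged, never deleted.

## Drift-diffusion core

Accuracy coding with an unbiased start (`z_rel = 0.5`) and unit diffusion;
the upper boundary is the correct response.  No inter-trial variability
parameters (`sv`, `sz`, `st`) are included, and no bias parameter: the
model's condition structure lives entirely in threshold and drift.
Collapsing bounds and time-varying drift are out of scope.

*Simulator.*  Euler-Maruyama with step `dt` (default 1 ms).  A naive
discrete scheme misses within-step boundary crossings and biases
first-passage times upward by O(sqrt(dt)); each step therefore also draws a
Brownian-bridge crossing indicator, `P(cross upper) =
exp(-2 (a - x)(a - x') / dt)` and analogously for the lower boundary, which
reduces the discretization bias to O(dt).  Paths not absorbed within 20 s
(practically nonexistent at sane parameters) are returned as omissions.

*Likelihood.*  The first-passage density at the lower boundary is evaluated
through the standard scaled form `f(t) = f0(t/a^2; w) / a^2 *
exp(-v a w - v^2 t_dec / 2)`, where `f0` has two series representations; the
implementation counts the terms each needs to bound the truncation error
below `err_tol` (default 1e-7) and uses the cheaper one.  The upper-boundary
density is the lower one under `(v, w) -> (-v, 1 - w)`.  Densities are 0 at
or below the non-decision time.  Simulator and density are cross-validated
in the tests by choice proportions against the closed-form absorption
probability `(1 - e^{-2 v z}) / (1 - e^{-2 v a})` and by the
Kolmogorov-Smirnov distance between the empirical and quadrature CDFs.

## Condition regression and estimation

The 16 cells of WM state x input x output x response switch are dummy-coded
against the maintenance/all-repeat reference, with updating frequency as an
additive main effect for both threshold and drift; non-decision time is one
free parameter per subject.

*Maximum likelihood* (`fit_mle`) exploits that the cells partition trials:
each (cell, frequency) group gets its own multi-start Nelder-Mead fit of
(log a, v, t); the shared non-decision time is then the trial-weighted
median of the group estimates, each group's (a, v) is re-optimized at that
fixed `t`, and coefficients are the trial-weighted least-squares projection
of the group parameters onto the intercept + cells (+ frequency) basis —
exact whenever the design is saturated.  Wald intervals come from the
per-group observed information propagated through the projection.  Cells
with fewer than 20 retained trials trigger a warning.

*Hierarchical Bayes* (`fit_hierarchical`).  Subject coefficients are normal
random effects around group means; priors are weakly-informative normals on
the group means (log-threshold intercept N(log 1.5, 1), drift intercept
N(2, 2^2), offsets N(0, 1) / N(0, 2^2), non-decision N(0.3, 0.2^2)) and
inverse-gamma(2, 0.1) on random-effect variances.  Threshold positivity is
guaranteed by a log link on `a`'s linear predictor.  The sampler is
Metropolis-within-Gibbs: per-coordinate random-walk Metropolis on each
subject's coefficients with step sizes adapted toward 44% acceptance during
burn-in (only the likelihood terms of the touched cells are recomputed),
and conjugate Gibbs updates for group means and variances.  The default
schedule mirrors standard practice for this model family: 4 chains, 3000
draws, 1000 burn-in, thin 2, hence 1000 retained draws per chain.  All
chains derive from one seed via spawned generators, so runs are exactly
reproducible.

Reporting: group coefficients are summarized by posterior mean and 95%
highest-density interval; an effect is called reliable when the HDI
excludes 0.  Identity-scale threshold effects are obtained by transforming
each posterior draw (`exp(mu_0 + mu_c) - exp(mu_0)`) rather than by a
delta-method linearization — the draw transform is exact for any monotone
function and keeps interval coverage.  R-hat is the classical potential
scale reduction `sqrt(((n-1)/n W + B/n) / W)` (identical chains give
exactly 1 up to the (n-1)/n factor, i.e. 1.000 at the reported precision).
DIC is `D-bar + p_D` with `p_D = D-bar - D(theta-bar)`, deviances summed
over subjects at subject-level draws.  The posterior-predictive check
simulates 50 datasets (matching the retained-draw convention for this kind
of check) at randomly drawn posterior parameters and compares group-level
signed-RT quantiles (errors negative, correct positive).

## Synthetic EEG

Epochs span -200..800 ms; generation at 500 Hz (500 samples) with FIR
anti-aliased decimation by 4 to 125 samples, or directly at 125 Hz where
speed matters.  A trial's signal is a sum of components, each a fixed
unit-norm topography times a Gaussian-bump or boxcar time course, with
amplitude `base + sum(modulators)` where modulators key on trial columns
(`input_switch`), level indicators (`category==symbol`), products
(`category==symbol & output_switch`) or `log_rt`.  Noise is Gaussian with
exponential spatial covariance over electrode distance (e-folding 8 cm) and
AR(1) temporal correlation (0.95 per 2 ms sample, rescaled when generating
at other rates); defaults (8 µV per-sample SD) give single-trial SNR in the
range typical of stimulus-locked scalp EEG.  Baseline correction subtracts
the prestimulus mean per trial and electrode.

The default component battery plants the signatures the analysis chain is
designed to find: parietal positivity ~350-500 ms gained by input switches,
frontal negativity ~250-350 ms gained by output switches, late parietal
positivity ~500-700 ms gained by response switches, category- and
action-coding topographies whose gain grows on the corresponding gate
switch, and a broad log-RT-coupled component so the RT nuisance regressor
has real signal to absorb.

What this generator does **not** emulate: real continuous-EEG preprocessing
(filtering, ICA, artifact rejection), volume-conduction forward physics,
non-stationary or non-Gaussian noise, eye movements, and between-subject
topographic variability.  Passing tests therefore certify the *statistical
machinery* — calibration, sensitivity, unbiasedness under a known truth —
not robustness to every property of real recordings.

The default montage is a 62-channel subset of the 10-10 system with
positions from MNE's standard head model; the adjacency threshold is chosen
automatically as the smallest distance whose median neighbor count reaches
6 (landing in the 6-8 range conventional for cluster tests).

## Mass-univariate GLM and cluster-mass permutation

Per subject, each electrode-time point of the z-scored epochs is regressed
on the design with an intercept using iteratively reweighted least squares
with Tukey bisquare weights (tuning 4.685, MAD scale), vectorized over all
points at once.  The robust scale has a floor of 1e-10 times the response
magnitude so numerically perfect fits don't turn rounding error into
"outliers".  Rank-deficient designs fail loudly, naming the collinear
columns.  The gating design is log RT, WM state, the three switches,
updating frequency and WM state x input switch (coded as the product of the
dummy columns); the representation design is log RT, WM state, category,
action.

Group inference is a one-sample t across subjects per point (zero-variance
points become NaN with a warning, never infinities).  Cluster-mass
correction: threshold at two-sided p = 0.001 (default), cluster positive
and negative excursions separately under spatiotemporal adjacency
(electrode neighbors, consecutive samples, and the diagonal combination),
score clusters by summed t, and build the null from the maximum absolute
cluster mass over subject-level sign flips (the exchangeable null for a
one-sample test; 1000 permutations by default, warning below 100).
Clusters are retained when their |mass| exceeds the null's 95th percentile;
building the null on max |mass| controls family-wise error across both
signs jointly.  Sign-flip t-maps are computed vectorized using the flip
invariance of per-subject squared values.

## Similarity indexing

A trial's similarity to a representation is the raw dot product between its
voltage map and the t-mask (no normalization by default: windows are
compared within, not across, positions; per-window normalization by mask
point count is available).  Sliding windows are 40 ms stepped by 8 ms —
5-sample windows advanced by 1 sample at 125 Hz, the first starting at
-200 ms with centers at window midpoints, giving 121 windows — and a window
is valid only where the mask has at least one significant point.  Masks are
expected from the representation design (category, action); gating-design
masks are not used for similarity.

Before the gating contrast, trials whose stimulus token repeats the
previous trial are excluded, so gate-repeat trials always involve a
perceptual change.  The discrimination index per window is the mean
similarity when the mask's coded level was probed minus when the other was
probed — already signed into the mask's preferred direction, since the
mask's t-values point toward the coded level.  The switch-vs-repeat
comparison defaults to a paired t across subjects on per-subject
switch-minus-repeat indices (a trial-pooled two-sample t is available for
single-subject use); windows are marked at p < .05, and windows with fewer
than two trials in any cell are returned indeterminate rather than tested.

## Behavioral ANOVA

`rm_anova` computes the classical fully-crossed within-subject partition
directly from marginal means by inclusion-exclusion: for each effect,
`SS_effect` from the de-marginalized effect estimates and `SS_error` from
their interaction with subjects; `F = MS_effect / MS_(effect x subject)`,
`eta_p^2 = SS_effect / (SS_effect + SS_error)`.  Degenerate designs are
well-defined: an effect with literally zero variance reports F = 0 (p = 1)
instead of a 0/0 artifact, and zero error variance with a real effect
reports F = inf.  RT cell means use correct, retained trials only (the
standard convention); error rates use all retained trials, untransformed.
The same engine accepts any fully-crossed factor set, so three-way and
five-way analyses run identically.  Sphericity corrections are omitted —
all factors of interest are two-level, where sphericity is moot.

## Problem sizes in the validation suite

The test and acceptance runs use synthetic scales chosen to make their
statistical claims meaningful while staying desk-sized: cluster FWER over
200 null experiments (30 subjects, 20 x 125 grids, 200 permutations),
sensitivity over 50 experiments with a d = 1.5 patch, DDM cross-validation
at 100,000 paths with 0.1 ms steps, threshold recovery over 30 subjects at
1000 trials per cell, prioritization recovery over 50 experiments of 10
subjects x 150 trials, and hierarchical-fit replications at 10 subjects x
150 trials per cell with 2 chains of 600 draws.  The full-scale default
schedule (4 x 3000 draws) is exercised structurally; power claims at those
reduced scales transfer qualitatively, not numerically, to other designs.

## Known limitations

- The MLE path estimates saturated cell parameters and projects onto the
  coefficient basis; with the additive frequency term and severely
  unbalanced cells this projection is approximate (exact when saturated).
- The sampler is a random-walk scheme: adequate for the desk-scale designs
  it ships with, but slow-mixing for large coefficient sets; random-effect
  variance parameters mix slowest and dominate R-hat on short chains.
- Similarity masks built from the same subjects' data as the contrast can
  in principle leak selection bias; the pipeline mitigates by using masks
  from a different design (representation vs gating), as intended, but no
  cross-validation split is enforced.
- The EEG generator's noise is stationary Gaussian; heavy-tailed artifacts
  that motivate the robust GLM are only exercised through injected
  outliers in the tests.
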