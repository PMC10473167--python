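# Methods

This note documents the models, conventions and numerical choices behind
`gazedyn`, in the order the pipeline runs them: stimulus and noise
generation, scanpath simulation, preprocessing, recurrence quantification,
and hierarchical inference.

## Stimulus generator

A stimulus is a 4-column x 5-row grid (cells 109 x 108 px, the interior
436 x 540 px centred on a 1920 x 1080 screen) containing `k` in 1..4 black
*segments*: horizontally or vertically contiguous runs of 1–4 filled cells.
Complexity is a property of the *occupancy grid*, not the construction:
`segment_count` returns the minimum number of straight runs covering the
black cells (exact branch-and-bound over candidate runs), so four cells in
a row count as one segment. The generator rejection-samples placements —
segment length and orientation uniform, position uniform among fitting
placements, overlap forbidden — until the recoverable count equals the
requested `k`; perpendicular touching is allowed, collinear adjacency that
would merge two runs is implicitly rejected by the count check. The probe
is a fair coin on colour, then uniform over cells of that colour. Corner
brackets are 12 px wide; the gap between grid and bracket defaults to 1 px
per side, which makes the full stimulus bounding box 462 x 566 px. The gap
is configurable because only the bounding box, not the exact bracket
offset, is pinned down by the display geometry.

## Dynamic visual noise

The noise field is 116 x 142 cells of 4 x 4 px (464 x 568 px, matching the
stimulus footprint). On a 144 Hz display updated every 4th frame there are
36 updates/s; a change rate of 50% of the 16 472 cells per second yields
`floor(0.5 * 16472 / 36) = 228` cell toggles per update, chosen uniformly
without replacement. The first frame is an independent 50/50 fill. One
boolean matrix is stored per update (72 frames for the 2-s exposure);
consecutive frames differ in exactly 228 cells by construction.

## Scanpath simulation

Maintenance scanpaths are generated by one of two mechanisms, or a
per-fixation mixture:

- **Restriction**: fixations are i.i.d. Gaussian around a single anchor
  (the pattern's black-cell centroid plus 30 px jitter) with per-axis
  dispersion `anchor_sd_px * restriction_release^(k-1)` — the restriction
  is *released* as complexity grows. Defaults: 45 px and 1.35, giving
  dispersions of 45/61/82/111 px for k = 1..4.
- **Reactivation**: fixations target segment centroids plus 25 px jitter.
  The visit process moves to an unvisited segment, or — with probability
  `revisit_prob` (default 0.3) — revisits a visited one. Revisit targets
  are drawn uniformly over visited segments, with a 0.2 share drawn in
  proportion to each segment's accumulated fixation count (trace
  strength). This blend makes the lag distribution of recurrent pairs
  match uniform pairing over the past, so the reactivation component is
  temporally neutral: CORM carries no complexity trend by construction,
  which is the behaviour the mixture is meant to exhibit. Visits are
  single fixations by default; longer visits would add short-lag recurrent
  pairs and pull CORM down at high complexity.
- **Mixture**: each fixation is a restriction draw with probability
  `w(k) = logistic(2.0 - 0.8 (k-1))` (0.88 at k=1 down to 0.40 at k=4),
  otherwise a reactivation draw. Simple images are held almost entirely by
  restriction; complex ones increasingly require place-bound refixations.

Fixation counts are Poisson with mean `rate x duration` (3 Hz x 20 s = 60;
a floor of 3 keeps recurrence defined), durations log-normal with median
300 ms and log-SD 0.35, clipped to the pipeline's own 100 ms–5 s filter
window, with a 30 ms inter-fixation gap; positions are clipped to the
screen. Under Gaussian restriction the high-recurrence/high-spread corner
of the spread-recurrence plane is empty *analytically*: recurrence above
50% requires the median pairwise distance (≈1.66 sigma) below the
threshold d, which forces the spread (median distance to centroid,
≈1.18 sigma) below d as well.

Per-participant heterogeneity enters as a log-normal multiplier (log-SD
0.5) on `anchor_sd_px` and a Gaussian shift (SD 0.8) on the *logit* of the
mixture weight. A shift on the logit rather than a multiplier on the
weight keeps the weight a probability; the two sources jointly reproduce
the large between-participant range of mean recurrence (roughly 10–95%
across seeds, ~24–81% at seed 1). A side effect worth knowing: because
both heterogeneity sources act multiplicatively on the same latent
quantities, participants with high baseline recurrence also show steeper
logit-scale declines, so the random intercept-slope correlation in the
fitted recurrence model is strongly negative in simulated data — a
property of this generator, not of the mechanism.

Responses: `P(correct) = logistic(3.2 - 0.45 k)` (≈88% overall accuracy,
declining with complexity); ratings are a latent normal `5.4 - 0.6 k`
(SD 1.5) rounded and clipped to 1..7, putting ≈19% of correct trials below
the rating-3 analysis threshold. Both match the orders of magnitude a
well-performing participant sample shows in this task.

What the generator does **not** emulate: saccade kinematics, measurement
noise and tracker loss (fixation retention is ~100%, unlike the ~85–90%
typical of real recordings), drift or non-stationarity within a trial,
stimulus-specific difficulty (each trial draws a fresh pattern, so
stimulus random intercepts are unidentifiable and default off), and any
effect of the noise factor (the DVN flag is carried through the design but
does not alter scanpaths — the null its models test). Passing tests
therefore demonstrate correctness of the machinery and internal
consistency of the mechanism logic, not fidelity to any particular
empirical dataset.

## Preprocessing

Fixations are dropped when off-screen (`x < 0`, `x >= width`, `y < 0`,
`y >= height`, centroid coordinates, no extent), shorter than 100 ms or
longer than 5 s; both duration bounds are kept inclusive. A fixation
failing several rules is counted once under the first rule in that order.
Spread is the median (even counts: mean of the two middle values) of
Euclidean distances to the unweighted centroid. Trials enter the analysis
only when answered correctly and rated at least 3 of 7. Filters apply
within the maintenance window only — the simulator emits nothing else.

## Recurrence quantification

Only the strict upper triangle (i < j) of the recurrence matrix is used;
the diagonal never counts. The distance threshold is inclusive (ties at
exactly d recur) and defaults to 2 degrees of visual angle converted
through the full trigonometric screen geometry (51 cm wide at 76 cm
viewing distance -> 103.5 px); `threshold_sweep` recomputes the per-trial
table across candidate thresholds since the foveal convention is exactly
that — a convention. Determinism uses maximal diagonal runs of length
>= L = 2. When R = 0, determinism and CORM are reported as 0 with a
`degenerate` flag, so the zeros are visible to the zero-inflated model
downstream rather than silently dropped.

## Hierarchical inference

The linear predictor is `eta = X beta + u0[p] + u1[p] * s`, with `s` the
mean-centred segment count (entered numerically, 1–4), correlated
participant intercepts/slopes, and an optional second random-intercept
grouping. Families:

- **Zero-one-inflated beta** for the RQA percentages (divided by 100):
  point mass `alpha` at {0, 1}, conditional probability `gamma` of a one,
  and a Beta component with logit-linked mean and precision `phi`;
  `alpha`, `gamma`, `phi` are intercept-only. Predictors act on the beta
  mean.
- **Ex-Gaussian** for spread: Normal(eta, sigma) + Exp(tau), predictors on
  the Gaussian location, `sigma` and `tau` intercept-only, log-linked.
- **Bernoulli** (logit) for trial-level accuracy.

Priors are weakly informative and data-scaled: Normal(0, 2.5) on
coefficients and Normal(0, 5) on the intercept (both multiplied by the
response SD for the identity-link family, with the intercept prior centred
on the response mean), half-Normal(1 or SD(y)) on random-effect SDs, an
LKJ(2)-type prior on the intercept-slope correlation, and Normal(centre,
3) on auxiliary parameters on their unconstrained scales.

**Posterior computation.** The default sampler is a nested Laplace
approximation in the tradition of lme4/glmmTMB/INLA: for fixed
hyperparameters (log-scales, correlation, auxiliaries) the latent block
(coefficients + non-centred effects) is a penalized GLM, solved by Newton
iterations with the analytic per-observation curvature of each family; the
latent block is integrated out via the Laplace determinant, and the
handful of hyperparameters are optimized on that marginal (L-BFGS-B with
finite-difference gradients, simplex fallback) under an explicit prior.
Hyperparameter uncertainty comes from a finite-difference Hessian of the
marginal at its mode (precision floored so no unconstrained draw SD
exceeds 3, the prior's own order); latent uncertainty from the Gaussian at
the inner mode. Draws rescale the non-centred z-block per hyperparameter
draw (`z' = L(phi_s)^{-1} L(phi_hat) z`) so that the natural-scale random
effects — which the data pin down — are preserved along the funnel.
A joint-mode Laplace was rejected: in the non-centred parameterization the
joint MAP rides the random-effect SD up to its prior scale regardless of
the data. The marginal approach was validated against glmmTMB (point
estimates and Wald intervals) and against emcee MCMC on the same log
posterior; `sampler="emcee"` remains available as the exact alternative.
Draws are arranged as 4 chains x 1000 (profile `test`) or 4 x 5000
(profile `full`) for arviz.

Known approximation limits: the credibility intervals of fixed effects
condition the latent covariance on the hyperparameter mode, so a small
share of hyperparameter uncertainty is not propagated into them; in the
recovery simulations at the reference design size this costs little
(coverage ~90–95%). Posterior intervals for variance parameters are
log-normal approximations.

**Model comparison** uses PSIS-LOO pointwise predictive densities (arviz)
on draws of the full linear predictor; the reported difference is
augmented minus reduced with the usual `sqrt(n var(d_i))` standard error.
**Posterior predictive checks** simulate replicate datasets from 100 draws
and report tail probabilities for the mean and SD. The **correlation
panel** across participant-level measures uses Pearson correlations with
Holm-adjusted p-values flagged at adjusted p < 0.01. The
**spread-recurrence quadrant summary** counts trials against a recurrence
cut of 50% and a spread cut at the recurrence threshold.

One generator limitation shows up in the participant-level correlation
panel: recurrence and determinism correlate near-perfectly across
simulated participants (both are driven by the same dispersion and mixture
heterogeneity), but CORM is deliberately mechanism-neutral and so carries
almost no between-participant variance — its correlations with the other
two measures are weak in simulation, whereas empirical populations show
all three temporal measures intercorrelated. Imagery ratings and span
scores are generated independently of the gaze mechanism and correlate
with nothing, as intended.

Open modelling choices resolved here: the spread covariate in the RQA
models is available (`include_spread_covariate`) but off by default — in
simulated data spread *mediates* the mechanism, so conditioning on it
absorbs the complexity effect by design; predictors enter as main effects
only; the stimulus-dispersion covariate (`stimulus_dispersion_px` in the
trial table) supports the looking-at-nothing confound probe.

## Problem sizes

The shipped defaults are the reference design (20 participants x 120
trials, 4 complexity levels; the noise factor splits 120 into 15-trial
cells). The test suite and the acceptance script run the full reference
design for the signature analysis, 1000 random scanpaths (N <= 60) for the
brute-force RQA comparison, 300 restriction and 40 reactivation trials for
the quadrant analyses, and 20 replicate fits per family for coverage; the
complete suite takes about three minutes on one CPU, the acceptance script
about two and a half.
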